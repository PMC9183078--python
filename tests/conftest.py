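import numpy as np
import pytest

from gaitpersona.segmentation import WindowSet
from gaitpersona.synthetic import GAIT, NONGAIT, make_profile, simulate_recording


@pytest.fixture(scope="session")
def typical_recording():
    """One typical-archetype labelled recording (120 s @ 100 Hz)."""
    profile = make_profile("typical", seed=11)
    return simulate_recording(profile, duration_s=120, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_window_set(labels, subject_id="S", n_per=None, w=200, rng_seed=0):
    """A WindowSet with given labels and random samples, for split/balance tests."""
    rng = np.random.default_rng(rng_seed)
    labels = np.asarray(labels, dtype=np.int8)
    return WindowSet(
        subject_id=subject_id,
        samples=rng.normal(size=(len(labels), w, 3)),
        labels=labels,
        starts=np.arange(len(labels)) * 0.4,
    )


def balanced_labels(n_each):
    return np.array([GAIT] * n_each + [NONGAIT] * n_each, dtype=np.int8)
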