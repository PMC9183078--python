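"""Per-window feature extraction for the feature-based classifier.

Each window is summarised by 8 statistics: the mean and the (population)
variance of the three axes x, y, z and of the per-sample vector magnitude
vm = sqrt(x^2 + y^2 + z^2).  Order is fixed as means then variances,
x, y, z, vm — the order the classifier and all fixtures assume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import Window, WindowSet
from .synthetic import LABEL_NAMES

__all__ = [
    "FEATURE_NAMES",
    "vector_magnitude",
    "extract_features",
    "feature_matrix",
    "feature_table",
]

FEATURE_NAMES = (
    "mean_x",
    "mean_y",
    "mean_z",
    "mean_vm",
    "var_x",
    "var_y",
    "var_z",
    "var_vm",
)


def vector_magnitude(x, y, z):
    """Euclidean norm of the three axes at one instant (vectorised)."""
    return np.sqrt(np.square(x) + np.square(y) + np.square(z))


def _features_from_array(samples: np.ndarray) -> np.ndarray:
    """Feature rows for a (n, w, 3) stack of windows."""
    vm = np.linalg.norm(samples, axis=-1)  # (n, w)
    means = samples.mean(axis=1)  # (n, 3)
    varis = samples.var(axis=1)  # population variance, ddof=0
    return np.column_stack(
        [means, vm.mean(axis=1), varis, vm.var(axis=1)]
    )


def extract_features(window: Window | np.ndarray) -> np.ndarray:
    """The 8-vector (mean_x..mean_vm, var_x..var_vm) for one window."""
    samples = window.samples if isinstance(window, Window) else np.asarray(window)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("a window must have shape (w, 3)")
    return _features_from_array(samples[None])[0]


def feature_matrix(windows: WindowSet) -> np.ndarray:
    """(n, 8) feature matrix for a window set, rows aligned with labels."""
    return _features_from_array(windows.samples)


def feature_table(windows: WindowSet) -> pd.DataFrame:
    """Feature CSV layout: subject_id,start_s,label + the 8 named features."""
    feats = feature_matrix(windows)
    df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    df.insert(0, "label", [LABEL_NAMES[c] for c in windows.labels])
    df.insert(0, "start_s", windows.starts)
    df.insert(0, "subject_id", windows.subject_id)
    return df
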