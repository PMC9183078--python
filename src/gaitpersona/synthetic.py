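"""Seeded simulation of labelled multi-subject accelerometer cohorts.

Real cohorts for gait studies in people with neurological conditions are
video-annotated clinical recordings that are rarely redistributable.  This
module generates stand-in cohorts with the same *shape*: 100 Hz tri-axial
acceleration in g, per-second gait / non-gait / unlabelled annotation,
subject-specific gait morphology (cadence, step amplitude, left/right
asymmetry, tremor), a minority of outlier subjects whose gait is severely
atypical, and the occasional vertically-flipped sensor mounting.

The signal model is deliberately simple — a gravity offset plus a
step-frequency sinusoid with one harmonic, amplitude alternating between
steps by ``(1 ± asymmetry)``, optional tremor, Gaussian noise, and slow
postural drifts during non-gait — not a biomechanical simulation.  Its only
obligation is to carry a learnable, subject-specific gait signature.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Archetype",
    "SubjectProfile",
    "AccelRecording",
    "LabelTrack",
    "GAIT",
    "NONGAIT",
    "UNLABELLED",
    "LABEL_NAMES",
    "make_profile",
    "simulate_recording",
    "make_cohort",
    "write_cohort",
]

# Integer label codes used throughout the pipeline.
GAIT = 1
NONGAIT = 0
UNLABELLED = -1
LABEL_NAMES = {GAIT: "gait", NONGAIT: "nongait", UNLABELLED: "unlabelled"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}


class Archetype(str, enum.Enum):
    """Gait-morphology archetype of a simulated subject."""

    TYPICAL = "typical"
    MILDLY_IMPAIRED = "mildly_impaired"
    OUTLIER = "outlier"


@dataclasses.dataclass(frozen=True)
class SubjectProfile:
    """Fixed per-subject parameters of the gait signal model.

    Amplitudes are in g, cadence in steps/min, tremor frequency in Hz.
    ``asymmetry`` in [0, 1] modulates alternate step amplitudes by
    ``(1 ± asymmetry)``.  ``flipped`` models an upside-down sensor mounting
    (the gravity-axis channel is negated).
    """

    subject_id: str
    archetype: Archetype
    cadence: float
    step_amplitude: float
    asymmetry: float
    tremor_amplitude: float
    tremor_freq: float
    noise_sd: float
    gravity_axis: str
    flipped: bool
    bout_mean_s: float
    seed: int

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        for name in ("step_amplitude", "tremor_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        if self.gravity_axis not in ("x", "y", "z"):
            raise ValueError(f"unknown gravity axis {self.gravity_axis!r}")


@dataclasses.dataclass(frozen=True)
class AccelRecording:
    """Uniformly sampled tri-axial acceleration stream for one subject.

    ``samples`` has shape (n, 3), columns x, y, z in g; sample k sits at time
    ``t0 + k / rate`` with ``t0 = 0`` for simulated data.
    """

    subject_id: str
    rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not np.isfinite(s).all():
            raise ValueError("samples contain non-finite values")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.rate if self.n_samples else 0.0


@dataclasses.dataclass(frozen=True)
class LabelTrack:
    """Per-second annotation: second i covers [i, i+1) from recording start."""

    labels: np.ndarray  # int codes GAIT / NONGAIT / UNLABELLED

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(lab, (GAIT, NONGAIT, UNLABELLED)).all():
            raise ValueError("labels must be gait/nongait/unlabelled codes")
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.labels)


# Archetype-specific uniform sampling ranges for profile parameters.
# Typical subjects carry a strong, fast, symmetric step signal that a general
# model trained on peers recognises easily; outliers are slow, weak-stepped,
# highly asymmetric and tremulous, so a peer-trained model misreads them —
# the cohort-level heterogeneity the personalisation protocol must expose.
_ARCHETYPE_RANGES = {
    Archetype.TYPICAL: dict(
        cadence=(95.0, 115.0),
        step_amplitude=(0.25, 0.45),
        asymmetry=(0.0, 0.1),
        tremor_amplitude=(0.0, 0.0),
        tremor_freq=(0.0, 0.0),
        noise_sd=(0.02, 0.05),
        bout_mean_s=(15.0, 30.0),
    ),
    Archetype.MILDLY_IMPAIRED: dict(
        cadence=(70.0, 95.0),
        step_amplitude=(0.15, 0.30),
        asymmetry=(0.1, 0.3),
        tremor_amplitude=(0.0, 0.05),
        tremor_freq=(4.0, 6.0),
        noise_sd=(0.03, 0.07),
        bout_mean_s=(12.0, 25.0),
    ),
    Archetype.OUTLIER: dict(
        cadence=(40.0, 70.0),
        step_amplitude=(0.08, 0.20),
        asymmetry=(0.3, 0.6),
        tremor_amplitude=(0.05, 0.15),
        tremor_freq=(4.0, 6.0),
        noise_sd=(0.05, 0.10),
        bout_mean_s=(8.0, 20.0),
    ),
}

_FLIP_PROBABILITY = 0.15  # occasional upside-down mounting


def make_profile(
    archetype: Archetype | str,
    seed: int,
    subject_id: str = "P0",
    gravity_axis: str = "y",
) -> SubjectProfile:
    """Draw a :class:`SubjectProfile` from the archetype's parameter ranges.

    The draw is fully determined by ``(archetype, seed)``; ``subject_id`` and
    ``gravity_axis`` are metadata that do not consume randomness.
    """
    archetype = Archetype(archetype)
    ranges = _ARCHETYPE_RANGES[archetype]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA5]))
    draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
    flipped = bool(rng.random() < _FLIP_PROBABILITY)
    return SubjectProfile(
        subject_id=subject_id,
        archetype=archetype,
        gravity_axis=gravity_axis,
        flipped=flipped,
        seed=int(seed),
        **draw,
    )


def _bout_schedule(
    rng: np.random.Generator, duration_s: float, bout_mean_s: float
) -> list[tuple[float, float, int]]:
    """Alternating (start, end, label) bouts tiling [0, duration_s].

    Bout lengths are exponential with the profile mean, floored at 3 s so that
    whole annotated seconds fit inside bouts and transition exclusion is
    exercised without dominating the corpus.
    """
    bouts = []
    label = GAIT if rng.random() < 0.5 else NONGAIT
    t = 0.0
    while t < duration_s:
        length = max(3.0, float(rng.exponential(bout_mean_s)))
        end = min(t + length, duration_s)
        bouts.append((t, end, label))
        t = end
        label = GAIT if label == NONGAIT else NONGAIT
    return bouts


def simulate_recording(
    profile: SubjectProfile,
    duration_s: float,
    seed: int,
    rate: float = 100.0,
) -> tuple[AccelRecording, LabelTrack]:
    """Simulate one labelled recording under a subject's gait model.

    Returns a uniformly sampled recording of ``duration_s * rate`` samples and
    a per-second label track.  Seconds split between two bouts are marked
    unlabelled, mirroring the granularity limit of per-second video
    annotation.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be at least 10 s")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E]))
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    axes = {"x": 0, "y": 1, "z": 2}
    g_ax = axes[profile.gravity_axis]
    others = [v for k, v in axes.items() if v != profile.gravity_axis]

    sig = np.zeros((n, 3))
    sig[:, g_ax] += 1.0  # gravity offset, in g

    bouts = _bout_schedule(rng, duration_s, profile.bout_mean_s)
    f_step = profile.cadence / 60.0
    for start, end, label in bouts:
        lo, hi = int(round(start * rate)), int(round(end * rate))
        tb = t[lo:hi] - start
        if label == GAIT:
            # alternate step amplitudes by (1 ± asymmetry); one harmonic
            step_idx = np.floor(tb * f_step).astype(int)
            amp = profile.step_amplitude * np.where(
                step_idx % 2 == 0, 1.0 + profile.asymmetry, 1.0 - profile.asymmetry
            )
            phase = rng.uniform(0, 2 * math.pi)
            wave = np.sin(2 * math.pi * f_step * tb + phase)
            wave += 0.4 * np.sin(4 * math.pi * f_step * tb + 2 * phase)
            sig[lo:hi, g_ax] += amp * wave
            for j, ax in enumerate(others):
                sh = phase + (j + 1) * math.pi / 2
                lateral = np.sin(2 * math.pi * f_step * tb + sh)
                lateral += 0.4 * np.sin(4 * math.pi * f_step * tb + 2 * sh)
                sig[lo:hi, ax] += 0.5 * amp * lateral
        else:
            # occasional slow postural drift: one low-frequency half-wave
            if rng.random() < 0.5:
                drift_amp = rng.uniform(0.02, 0.1)
                drift_f = rng.uniform(0.05, 0.2)
                drift_ph = rng.uniform(0, 2 * math.pi)
                ax = rng.choice(3)
                sig[lo:hi, ax] += drift_amp * np.sin(
                    2 * math.pi * drift_f * tb + drift_ph
                )
    if profile.tremor_amplitude > 0:
        for ax in range(3):
            ph = rng.uniform(0, 2 * math.pi)
            sig[:, ax] += profile.tremor_amplitude * np.sin(
                2 * math.pi * profile.tremor_freq * t + ph
            )
    sig += rng.normal(0.0, profile.noise_sd, size=sig.shape)
    if profile.flipped:
        sig[:, g_ax] = -sig[:, g_ax]

    # per-second labels: a second gets a bout's label iff wholly inside it
    n_seconds = int(math.floor(duration_s))
    labels = np.full(n_seconds, UNLABELLED, dtype=np.int8)
    for start, end, label in bouts:
        first = int(math.ceil(start - 1e-9))
        last = int(math.floor(end + 1e-9))  # seconds [first, last) inside bout
        labels[first : min(last, n_seconds)] = label

    rec = AccelRecording(subject_id=profile.subject_id, rate=rate, samples=sig)
    return rec, LabelTrack(labels)


def make_cohort(
    n_subjects: int,
    outlier_fraction: float,
    duration_s: float,
    base_seed: int,
    rate: float = 100.0,
) -> list[tuple[SubjectProfile, AccelRecording, LabelTrack]]:
    """Generate a deterministic multi-subject cohort.

    ``round(n_subjects * outlier_fraction)`` subjects (the last ones by id)
    use the outlier archetype; the rest are typical.  Subject ids are
    ``P0 ... P{n-1}``; all per-subject seeds derive from ``base_seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for leave-one-out")
    if not 0.0 <= outlier_fraction <= 1.0:
        raise ValueError("outlier_fraction must lie in [0, 1]")
    n_outliers = int(round(n_subjects * outlier_fraction))
    ss = np.random.SeedSequence(int(base_seed))
    subject_seeds = ss.generate_state(2 * n_subjects) % (2**31)
    cohort = []
    for i in range(n_subjects):
        archetype = (
            Archetype.OUTLIER if i >= n_subjects - n_outliers else Archetype.TYPICAL
        )
        profile = make_profile(
            archetype, int(subject_seeds[2 * i]), subject_id=f"P{i}"
        )
        rec, track = simulate_recording(
            profile, duration_s, int(subject_seeds[2 * i + 1]), rate=rate
        )
        cohort.append((profile, rec, track))
    return cohort


def write_cohort(
    cohort: list[tuple[SubjectProfile, AccelRecording, LabelTrack]],
    out_dir: str | Path,
) -> dict:
    """Write per-subject recording/label CSVs plus a JSON manifest.

    Formats match what the real-data reader consumes: ``<id>_recording.csv``
    with columns time_s,x,y,z (6-decimal fixed point) and ``<id>_labels.csv``
    with columns second_index,label.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": []}
    for profile, rec, track in cohort:
        t = rec.t0 + np.arange(rec.n_samples) / rec.rate
        df = pd.DataFrame(
            {"time_s": t, "x": rec.samples[:, 0], "y": rec.samples[:, 1],
             "z": rec.samples[:, 2]}
        )
        rec_path = out_dir / f"{profile.subject_id}_recording.csv"
        df.to_csv(rec_path, index=False, float_format="%.6f")
        lab = pd.DataFrame(
            {
                "second_index": np.arange(len(track)),
                "label": [LABEL_NAMES[c] for c in track.labels],
            }
        )
        lab_path = out_dir / f"{profile.subject_id}_labels.csv"
        lab.to_csv(lab_path, index=False)
        manifest["subjects"].append(
            {
                "subject_id": profile.subject_id,
                "archetype": profile.archetype.value,
                "recording": rec_path.name,
                "labels": lab_path.name,
                "rate": rec.rate,
                "flipped": profile.flipped,
                "gravity_axis": profile.gravity_axis,
            }
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
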