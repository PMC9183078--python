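"""Canonicalise raw recordings: 100 Hz uniform, flip-corrected, sample labels.

The pipeline's canonical form is a uniformly sampled 100 Hz stream whose
gravity axis reads positive on average, with the per-second annotation
expanded to per-sample resolution.  Device calibration against a reference
(inter-device bias removal) is exposed as :func:`calibrate` but is an
identity hook: the simulated cohorts carry no device bias to remove.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    GAIT,
    LABEL_CODES,
    NONGAIT,
    UNLABELLED,
    AccelRecording,
    LabelTrack,
)

__all__ = [
    "resample_linear",
    "correct_vertical_flip",
    "infer_gravity_axis",
    "calibrate",
    "label_samples",
    "read_recording_csv",
    "read_label_csv",
]

_AXES = {"x": 0, "y": 1, "z": 2}


def resample_linear(
    recording: AccelRecording,
    target_rate: float = 100.0,
    times: np.ndarray | None = None,
) -> AccelRecording:
    """Resample to a uniform grid by per-axis linear interpolation.

    The output grid is ``t0 + k / target_rate`` for
    ``k = 0 .. floor((t_end - t0) * target_rate)``; no extrapolation beyond
    the input range.  ``times`` supplies the input timestamps when the source
    was not uniformly sampled; by default samples are assumed uniform at
    ``recording.rate``.
    """
    if recording.n_samples < 2:
        raise ValueError("resampling needs at least 2 samples")
    if times is None:
        times = recording.t0 + np.arange(recording.n_samples) / recording.rate
    else:
        times = np.asarray(times, dtype=float)
        if times.shape != (recording.n_samples,):
            raise ValueError("times must match the sample count")
        if not (np.diff(times) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
    t0, t_end = times[0], times[-1]
    n_out = int(np.floor((t_end - t0) * target_rate + 1e-9)) + 1
    grid = t0 + np.arange(n_out) / target_rate
    out = np.column_stack(
        [np.interp(grid, times, recording.samples[:, ax]) for ax in range(3)]
    )
    return AccelRecording(
        subject_id=recording.subject_id, rate=target_rate, samples=out, t0=t0
    )


def infer_gravity_axis(recording: AccelRecording) -> str:
    """Axis with the largest absolute mean — where gravity's 1 g offset sits."""
    means = recording.samples.mean(axis=0)
    return "xyz"[int(np.argmax(np.abs(means)))]


def correct_vertical_flip(
    recording: AccelRecording, gravity_axis: str | None = None
) -> AccelRecording:
    """Negate the gravity-axis channel if its mean is negative.

    An upside-down sensor mounting reads gravity as -1 g; multiplying that
    channel by -1 restores the canonical orientation.  Idempotent; other
    channels are never touched.  With ``gravity_axis=None`` the axis is
    inferred as the one carrying the largest absolute mean.
    """
    if gravity_axis is None:
        gravity_axis = infer_gravity_axis(recording)
    if gravity_axis not in _AXES:
        raise ValueError(f"unknown gravity axis {gravity_axis!r}")
    ax = _AXES[gravity_axis]
    if recording.samples[:, ax].mean() >= 0:
        return recording
    out = recording.samples.copy()
    out[:, ax] = -out[:, ax]
    return AccelRecording(
        subject_id=recording.subject_id,
        rate=recording.rate,
        samples=out,
        t0=recording.t0,
    )


def calibrate(recording: AccelRecording) -> AccelRecording:
    """Device-calibration hook; identity for simulated data.

    Real multi-device studies estimate per-device gain/offset so different
    sensors agree under identical conditions.  The simulator emits unbiased
    signals, so there is nothing to estimate; the hook exists so a real-data
    deployment has a seam to plug a calibration into.
    """
    return recording


def label_samples(
    track: LabelTrack, n_samples: int, rate: float
) -> np.ndarray:
    """Expand per-second labels to per-sample labels.

    Sample k takes the label of second ``floor(k / rate)``; samples beyond
    the annotated track (a trailing partial second) are unlabelled.
    """
    n_track = len(track)
    if n_samples > n_track * rate + rate:
        raise ValueError(
            f"{n_samples} samples exceed the label track "
            f"({n_track} s at {rate} Hz) by more than one second"
        )
    second = np.floor(np.arange(n_samples) / rate).astype(int)
    out = np.full(n_samples, UNLABELLED, dtype=np.int8)
    inside = second < n_track
    out[inside] = track.labels[second[inside]]
    return out


def read_recording_csv(path: str | Path, subject_id: str | None = None) -> tuple[AccelRecording, np.ndarray]:
    """Read a recording CSV (columns time_s,x,y,z).

    Returns the recording plus its raw timestamp vector (the source may be
    non-uniform; feed both to :func:`resample_linear`).  Malformed rows raise
    with the offending line number (1-based, counting the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["time_s", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    for col in expected:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) >= 2 and not (np.diff(times) > 0).all():
        line = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 3
        raise ValueError(f"{path}: timestamps not strictly increasing at line {line}")
    dt = np.median(np.diff(times)) if len(times) > 1 else 1.0
    rec = AccelRecording(
        subject_id=subject_id or path.stem.replace("_recording", ""),
        rate=1.0 / dt,
        samples=df[["x", "y", "z"]].to_numpy(dtype=float),
        t0=float(times[0]) if len(times) else 0.0,
    )
    return rec, times


def read_label_csv(path: str | Path) -> LabelTrack:
    """Read a label CSV (columns second_index,label) into a LabelTrack."""
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["second_index", "label"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    unknown = ~df["label"].isin(LABEL_CODES)
    if unknown.any():
        line = int(np.flatnonzero(unknown.to_numpy())[0]) + 2
        raise ValueError(f"{path}: unknown label at line {line}")
    idx = df["second_index"].to_numpy(dtype=int)
    if not (idx == np.arange(len(idx))).all():
        raise ValueError(f"{path}: second_index must run 0..n-1 without gaps")
    codes = df["label"].map(LABEL_CODES).to_numpy(dtype=np.int8)
    return LabelTrack(codes)
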