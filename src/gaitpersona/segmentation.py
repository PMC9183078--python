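"""Overlapping-window segmentation with transition exclusion and balancing.

A labelled recording is cut into 2-s windows starting every 0.4 s.  A window
is kept only if every covered sample carries the same gait/non-gait label;
windows touching a transition or any unlabelled second are discarded, which
sidesteps the per-second granularity of the annotation.  Class balance is
then restored by randomly undersampling the majority class.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .synthetic import GAIT, LABEL_NAMES, NONGAIT, UNLABELLED, AccelRecording

__all__ = ["Window", "WindowSet", "slide_windows", "undersample_balance"]


@dataclasses.dataclass(frozen=True)
class Window:
    """One labelled segment: (window_s * rate) x 3 samples in g."""

    subject_id: str
    start_s: float
    samples: np.ndarray
    label: int  # GAIT or NONGAIT


@dataclasses.dataclass(frozen=True)
class WindowSet:
    """A stack of labelled windows from one subject.

    ``samples`` has shape (n, w, 3); ``labels`` and ``starts`` align with its
    first axis.  Indexing returns a :class:`Window` view.
    """

    subject_id: str
    samples: np.ndarray
    labels: np.ndarray
    starts: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.samples) == len(self.labels) == len(self.starts)):
            raise ValueError("samples, labels and starts must align")
        if np.isin(self.labels, UNLABELLED).any():
            raise ValueError("a WindowSet never contains unlabelled windows")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> Window:
        return Window(
            subject_id=self.subject_id,
            start_s=float(self.starts[i]),
            samples=self.samples[i],
            label=int(self.labels[i]),
        )

    def select(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            self.subject_id, self.samples[idx], self.labels[idx], self.starts[idx]
        )

    def class_counts(self) -> dict[int, int]:
        return {
            GAIT: int((self.labels == GAIT).sum()),
            NONGAIT: int((self.labels == NONGAIT).sum()),
        }

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a CSV-friendly table: start_s,label,x0..,y0..,z0.."""
        w = self.samples.shape[1]
        cols = {}
        cols["start_s"] = self.starts
        cols["label"] = [LABEL_NAMES[c] for c in self.labels]
        for ax_i, ax in enumerate("xyz"):
            for k in range(w):
                cols[f"{ax}{k}"] = self.samples[:, k, ax_i]
        return pd.DataFrame(cols)


def slide_windows(
    recording: AccelRecording,
    sample_labels: np.ndarray,
    window_s: float = 2.0,
    stride_s: float = 0.4,
) -> WindowSet:
    """Emit every pure candidate window, in start-time order.

    Candidates start at 0, stride_s, 2*stride_s, ... while the full window
    fits; a candidate survives iff all covered samples share one label and
    that label is not unlabelled.
    """
    rate = recording.rate
    w = window_s * rate
    s = stride_s * rate
    if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
        raise ValueError(
            f"window ({window_s}s) and stride ({stride_s}s) must cover whole "
            f"samples at {rate} Hz"
        )
    w, s = int(round(w)), int(round(s))
    labels = np.asarray(sample_labels)
    if len(labels) != recording.n_samples:
        raise ValueError("sample_labels length must match the recording")
    n = recording.n_samples
    if n < w:
        empty = np.empty((0, w, 3))
        return WindowSet(recording.subject_id, empty, np.empty(0, np.int8), np.empty(0))

    lab_view = np.lib.stride_tricks.sliding_window_view(labels, w)[::s]
    pure = (lab_view.min(axis=1) == lab_view.max(axis=1)) & (
        lab_view[:, 0] != UNLABELLED
    )
    sig_view = np.lib.stride_tricks.sliding_window_view(
        recording.samples, (w, 3)
    ).squeeze(axis=1)[::s]
    starts = np.arange(len(pure)) * stride_s
    return WindowSet(
        subject_id=recording.subject_id,
        samples=sig_view[pure].copy(),
        labels=lab_view[pure, 0].astype(np.int8),
        starts=starts[pure],
    )


def undersample_balance(windows: WindowSet, seed: int) -> WindowSet:
    """Randomly drop majority-class windows until classes are equal.

    The minority class is untouched and the surviving windows keep their
    original order.  Raises when a class is absent (the subject cannot feed a
    balanced two-class protocol).
    """
    counts = windows.class_counts()
    if counts[GAIT] == 0 or counts[NONGAIT] == 0:
        raise ValueError(
            f"subject {windows.subject_id}: both classes required to balance, "
            f"got {counts[GAIT]} gait / {counts[NONGAIT]} non-gait windows"
        )
    if counts[GAIT] == counts[NONGAIT]:
        return windows
    majority = GAIT if counts[GAIT] > counts[NONGAIT] else NONGAIT
    n_keep = min(counts.values())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA]))
    maj_idx = np.flatnonzero(windows.labels == majority)
    kept_maj = np.sort(rng.choice(maj_idx, size=n_keep, replace=False))
    keep = np.sort(
        np.concatenate([np.flatnonzero(windows.labels != majority), kept_maj])
    )
    return windows.select(keep)
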