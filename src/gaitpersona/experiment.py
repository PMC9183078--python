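"""Leave-one-subject-out comparison of general vs personalised models.

For each held-out subject a *general* model is trained on the pooled,
balanced windows of all other subjects.  Part of the held-out subject's own
data (a seeded stratified split) then fine-tunes a copy of that model at a
small learning rate — the *personalised* model — and both are scored on the
remaining personal windows.  The whole protocol is repeated several times
with repetition-derived seeds (perturbing the init/shuffling of pretraining,
the personal split, and the fine-tuning) and averaged, since single runs of
small networks are noisy.

Accuracy is the proportion of correctly classified windows; every split is
balanced, so chance level is 0.5 throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
import pandas as pd

from .features import feature_matrix
from .models import (
    CNNGaitClassifier,
    NNGaitClassifier,
    TrainConfig,
    train_with_retries,
)
from .preprocessing import (
    correct_vertical_flip,
    label_samples,
    resample_linear,
)
from .segmentation import WindowSet, slide_windows, undersample_balance

__all__ = [
    "FoldResult",
    "StudyReport",
    "accuracy",
    "split_personal",
    "pretrain_general",
    "fine_tune",
    "run_loo",
    "cohort_windows",
    "audit_no_leakage",
    "default_train_config",
]

DEFAULT_TRAIN = {
    "nn": TrainConfig(learning_rate=0.05, epochs=150, batch_size=32),
    "cnn": TrainConfig(learning_rate=0.01, epochs=60, batch_size=32),
}
DEFAULT_TUNE_FRACTION = 0.6


def default_train_config(model_kind: str) -> TrainConfig:
    return DEFAULT_TRAIN[model_kind]


@dataclasses.dataclass(frozen=True)
class FoldResult:
    """One (subject, repetition) comparison, both models scoring one eval set."""

    subject_id: str
    repetition: int
    model_kind: str
    general_accuracy: float
    personalised_accuracy: float
    n_tune: int
    n_eval: int
    # bookkeeping for the leakage audit
    pretrain_subjects: tuple[str, ...] = ()
    tune_starts: tuple[float, ...] = ()
    eval_starts: tuple[float, ...] = ()


@dataclasses.dataclass
class StudyReport:
    """All folds of one LOO study plus its configuration snapshot."""

    folds: list[FoldResult]
    config: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": f.subject_id,
                    "repetition": f.repetition,
                    "model_kind": f.model_kind,
                    "general_accuracy": f.general_accuracy,
                    "personalised_accuracy": f.personalised_accuracy,
                    "n_tune": f.n_tune,
                    "n_eval": f.n_eval,
                }
                for f in self.folds
            ]
        )

    def per_subject(self) -> pd.DataFrame:
        """Per-subject means over repetitions, one row per (subject, model)."""
        df = self.to_frame()
        out = (
            df.groupby(["subject_id", "model_kind"], as_index=False)
            .agg(
                mean_general=("general_accuracy", "mean"),
                mean_personalised=("personalised_accuracy", "mean"),
            )
            .sort_values(["model_kind", "subject_id"], ignore_index=True)
        )
        out["improvement"] = out["mean_personalised"] - out["mean_general"]
        return out

    def overall(self) -> pd.DataFrame:
        """Cohort summary per model kind.

        ``mean_*`` columns are unweighted means of the per-subject means;
        ``weighted_*`` weight each fold by its evaluation-window count.
        """
        per = self.per_subject()
        rows = []
        folds = self.to_frame()
        for kind, sub in per.groupby("model_kind"):
            fsub = folds[folds.model_kind == kind]
            w = fsub["n_eval"].to_numpy(float)
            rows.append(
                {
                    "model_kind": kind,
                    "mean_general": sub["mean_general"].mean(),
                    "mean_personalised": sub["mean_personalised"].mean(),
                    "mean_improvement": sub["improvement"].mean(),
                    "max_improvement": sub["improvement"].max(),
                    "max_improvement_subject": sub.loc[
                        sub["improvement"].idxmax(), "subject_id"
                    ],
                    "min_improvement": sub["improvement"].min(),
                    "weighted_general": np.average(
                        fsub["general_accuracy"], weights=w
                    ),
                    "weighted_personalised": np.average(
                        fsub["personalised_accuracy"], weights=w
                    ),
                }
            )
        return pd.DataFrame(rows)


def accuracy(predictions, truth) -> float:
    """Proportion of correctly classified windows."""
    predictions = np.asarray(predictions).ravel()
    truth = np.asarray(truth).ravel()
    if len(predictions) == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth lengths differ")
    return float(np.mean(predictions == truth))


def split_personal(
    windows: WindowSet, tune_fraction: float, seed: int
) -> tuple[WindowSet, WindowSet]:
    """Seeded stratified split of one subject's windows into tune and eval.

    Within each class, ``round(tune_fraction * class_size)`` windows go to
    the tune set; the rest form the eval set.  Disjoint, order-preserving,
    union = input.
    """
    if not 0.0 < tune_fraction < 1.0:
        raise ValueError("tune_fraction must lie strictly inside (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F]))
    tune_idx = []
    for cls, count in windows.class_counts().items():
        if count < 2:
            raise ValueError(
                f"subject {windows.subject_id}: class {cls} has {count} "
                "window(s); need at least 2 to split"
            )
        idx = np.flatnonzero(windows.labels == cls)
        n_tune = int(round(tune_fraction * len(idx)))
        n_tune = min(max(n_tune, 1), len(idx) - 1)  # both parts non-empty
        tune_idx.append(rng.choice(idx, size=n_tune, replace=False))
    tune_idx = np.sort(np.concatenate(tune_idx))
    mask = np.zeros(len(windows), dtype=bool)
    mask[tune_idx] = True
    return windows.select(np.flatnonzero(mask)), windows.select(np.flatnonzero(~mask))


def _design(windows: WindowSet, model_kind: str) -> np.ndarray:
    if model_kind == "nn":
        return feature_matrix(windows)
    if model_kind == "cnn":
        return windows.samples
    raise ValueError(f"unknown model kind {model_kind!r}")


def _builder(model_kind: str, config: TrainConfig) -> Callable:
    common = dict(
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        stuck_threshold=config.stuck_threshold,
        max_retrains=1,
    )
    if model_kind == "nn":
        return lambda seed: NNGaitClassifier(random_state=seed, **common)
    return lambda seed: CNNGaitClassifier(random_state=seed, **common)


def pretrain_general(
    windows_by_subject: dict[str, WindowSet],
    held_out: str,
    model_kind: str,
    config: TrainConfig | None = None,
):
    """Train the general model on every subject except ``held_out``."""
    if held_out not in windows_by_subject:
        raise ValueError(f"held-out subject {held_out!r} not in cohort")
    others = {s: w for s, w in windows_by_subject.items() if s != held_out}
    if not others:
        raise ValueError("leave-one-out needs at least one other subject")
    if config is None:
        config = default_train_config(model_kind)
    X = np.concatenate([_design(w, model_kind) for w in others.values()])
    y = np.concatenate([w.labels for w in others.values()])
    return train_with_retries(_builder(model_kind, config), X, y, config)


def fine_tune(pretrained, tune_set: WindowSet, ft_config: TrainConfig):
    """Personalise a copy of the general model on one subject's tune windows."""
    if ft_config.learning_rate >= pretrained.learning_rate:
        raise ValueError(
            "fine-tune learning rate must be smaller than the general rate"
        )
    kind = "nn" if isinstance(pretrained, NNGaitClassifier) else "cnn"
    return pretrained.fine_tuned(
        _design(tune_set, kind),
        tune_set.labels,
        learning_rate=ft_config.learning_rate,
        epochs=ft_config.epochs,
        seed=ft_config.seed,
    )


def run_loo(
    windows_by_subject: dict[str, WindowSet],
    model_kind: str = "nn",
    train_config: TrainConfig | None = None,
    ft_config: TrainConfig | None = None,
    tune_fraction: float = DEFAULT_TUNE_FRACTION,
    n_repetitions: int = 5,
    base_seed: int = 0,
) -> StudyReport:
    """The full protocol: pretrain, personalise and score every subject.

    For every subject x repetition, the repetition index perturbs the seeds
    of the general-model init/shuffling, the personal tune/eval split and
    the fine-tuning, and both models score the same eval set.
    """
    if len(windows_by_subject) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    if train_config is None:
        train_config = default_train_config(model_kind)
    # fine-tuning default: same epoch count at a 10x smaller rate — enough
    # steps to adapt to a severely atypical subject while only tweaking
    if ft_config is None:
        ft_config = dataclasses.replace(
            train_config, learning_rate=0.1 * train_config.learning_rate
        )
    folds: list[FoldResult] = []
    subjects = sorted(windows_by_subject)
    for si, subject in enumerate(subjects):
        for rep in range(n_repetitions):
            seeds = np.random.SeedSequence(
                [int(base_seed), si, rep]
            ).generate_state(3) % (2**31)
            try:
                general = pretrain_general(
                    windows_by_subject,
                    subject,
                    model_kind,
                    dataclasses.replace(train_config, seed=int(seeds[0])),
                )
                tune_set, eval_set = split_personal(
                    windows_by_subject[subject], tune_fraction, int(seeds[1])
                )
                personal = fine_tune(
                    general,
                    tune_set,
                    dataclasses.replace(ft_config, seed=int(seeds[2])),
                )
                X_eval = _design(eval_set, model_kind)
                gen_acc = accuracy(general.predict(X_eval), eval_set.labels)
                per_acc = accuracy(personal.predict(X_eval), eval_set.labels)
            except ValueError as err:
                raise ValueError(
                    f"subject {subject}, repetition {rep}: {err}"
                ) from err
            folds.append(
                FoldResult(
                    subject_id=subject,
                    repetition=rep,
                    model_kind=model_kind,
                    general_accuracy=gen_acc,
                    personalised_accuracy=per_acc,
                    n_tune=len(tune_set),
                    n_eval=len(eval_set),
                    pretrain_subjects=tuple(s for s in subjects if s != subject),
                    tune_starts=tuple(tune_set.starts),
                    eval_starts=tuple(eval_set.starts),
                )
            )
    config = {
        "model_kind": model_kind,
        "train_config": dataclasses.asdict(train_config),
        "ft_config": dataclasses.asdict(ft_config),
        "tune_fraction": tune_fraction,
        "n_repetitions": n_repetitions,
        "base_seed": base_seed,
        "n_subjects": len(subjects),
        "feature_standardisation": model_kind == "nn",
    }
    return StudyReport(folds=folds, config=config)


def audit_no_leakage(report: StudyReport) -> None:
    """Assert protocol hygiene on every fold.

    The held-out subject never appears in its own pretraining pool, the
    tune/eval partition is disjoint and exhaustive per fold, and both counts
    are positive.  Raises ``AssertionError`` on any violation.
    """
    for f in report.folds:
        assert f.subject_id not in f.pretrain_subjects, (
            f"{f.subject_id} leaked into its own pretraining pool"
        )
        tune, evl = set(f.tune_starts), set(f.eval_starts)
        assert not tune & evl, f"{f.subject_id}: tune and eval windows overlap"
        assert f.n_tune == len(tune) > 0 and f.n_eval == len(evl) > 0


def cohort_windows(
    cohort,
    seed: int = 0,
    target_rate: float = 100.0,
    window_s: float = 2.0,
    stride_s: float = 0.4,
    gravity_axis: str | None = None,
) -> dict[str, WindowSet]:
    """Run the preprocessing pipeline over a cohort, per subject.

    ``cohort`` is an iterable of ``(profile_or_None, recording, track)``.
    Each recording is resampled to ``target_rate``, flip-corrected,
    windowed and balanced (per-subject balancing keeps every LOO pool and
    personal split at chance level 0.5).
    """
    out: dict[str, WindowSet] = {}
    sub_seeds = np.random.SeedSequence([int(seed), 0xC0]).generate_state(
        max(len(cohort), 1)
    ) % (2**31)
    for i, (_, rec, track) in enumerate(cohort):
        rec = resample_linear(rec, target_rate)
        rec = correct_vertical_flip(rec, gravity_axis)
        labels = label_samples(track, rec.n_samples, rec.rate)
        ws = slide_windows(rec, labels, window_s, stride_s)
        out[rec.subject_id] = undersample_balance(ws, int(sub_seeds[i]))
    return out
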