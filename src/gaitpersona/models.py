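"""The two window classifiers: an 8-feature NN and a raw-window 1-D CNN.

Both are scikit-learn style estimators over the numpy core in ``_net``:

* :class:`NNGaitClassifier` — 8 features -> 4 sigmoid units -> 1 output
  (41 trainable parameters).  Features are z-scored by default with
  statistics taken from the *training* pool only, because sigmoid units
  saturate on raw g^2-scale variances.
* :class:`CNNGaitClassifier` — (200, 3) raw window -> conv1d(8 filters,
  kernel 32) -> maxpool(3) -> dropout(0.2) -> conv1d(8 filters, kernel 16)
  -> maxpool(3) -> dropout(0.2) -> flatten -> dense(3) -> 1 output.  Hidden
  activations are ReLU; the single output unit is a sigmoid so the model
  expresses a two-class probability under cross-entropy.

Training is seeded mini-batch gradient descent on binary cross-entropy,
with the stuck-model rule: a fit whose final training accuracy stays below
``stuck_threshold`` is discarded and retrained from a freshly derived seed,
up to ``max_retrains`` attempts (the best attempt is kept, with a warning,
if all stay stuck).  Identical data + hyperparameters give bit-identical
models.  Fine-tuning (:meth:`fine_tuned`) continues training a *copy* at a
smaller learning rate, leaving the general model untouched.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
import numbers
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._net import Conv1D, Dense, Dropout, Flatten, MaxPool1D, Network, sigmoid

__all__ = [
    "TrainConfig",
    "NNGaitClassifier",
    "CNNGaitClassifier",
    "build_nn",
    "build_cnn",
    "nn_forward",
    "cnn_forward",
    "train",
    "train_with_retries",
    "count_parameters",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

WINDOW_LEN = 200  # samples per 2-s window at 100 Hz
N_FEATURES = 8


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training session."""

    learning_rate: float = 0.05
    epochs: int = 150
    batch_size: int = 32
    seed: int = 0
    stuck_threshold: float = 0.6
    max_retrains: int = 5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if not 0.5 <= self.stuck_threshold < 1.0:
            raise ValueError("stuck_threshold must lie in [0.5, 1)")


def _derived_rng(seed: int, attempt: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), attempt, tag]))


class _BaseGaitClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing; subclasses define the layer stack."""

    _dtype = np.float64  # CNN overrides with float32 for training speed

    def __init__(
        self,
        learning_rate: float,
        epochs: int,
        batch_size: int = 32,
        random_state: int = 0,
        stuck_threshold: float = 0.6,
        max_retrains: int = 5,
    ):
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state
        self.stuck_threshold = stuck_threshold
        self.max_retrains = max_retrains

    # subclass API ----------------------------------------------------------
    def _build_network(self) -> Network:  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_X(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return X

    def _fit_scaler(self, X: np.ndarray) -> None:
        pass

    # construction ----------------------------------------------------------
    def initialize(self, seed: int | None = None, attempt: int = 0):
        """Build the network with seeded symmetric-uniform weights, zero biases."""
        if seed is None:
            seed = self.random_state
        self.net_ = self._build_network()
        self.net_.init(_derived_rng(seed, attempt, 0x11))
        self.net_.astype(self._dtype)
        self.classes_ = np.array([0, 1])
        self.history_ = {"loss": np.empty(0), "accuracy": np.empty(0)}
        return self

    # training --------------------------------------------------------------
    def _train_once(self, X, y, lr, epochs, batch_size, rng):
        hist = self.net_.fit_sgd(X, y, lr, epochs, batch_size, rng)
        self.history_ = {
            k: np.concatenate([self.history_[k], hist[k]]) for k in hist
        }
        return hist

    def fit(self, X, y):
        """Train from a fresh seeded init, applying the stuck-retrain rule."""
        X = self._check_X(X)
        y = np.asarray(y, dtype=int).ravel()
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self._fit_scaler(X)
        Xt = self._transform(X)
        best = None
        n_attempts = max(1, int(self.max_retrains)) if self.epochs > 0 else 1
        for attempt in range(n_attempts):
            self.initialize(self.random_state, attempt=attempt)
            hist = self._train_once(
                Xt,
                y,
                self.learning_rate,
                self.epochs,
                self.batch_size,
                _derived_rng(self.random_state, attempt, 0x22),
            )
            # running accuracy of the final epoch; avoids an extra full pass
            if len(hist["accuracy"]):
                acc = float(hist["accuracy"][-1])
            else:
                acc = float(
                    np.mean((self.net_.predict_proba(Xt) > 0.5).astype(int) == y)
                )
            self.final_train_accuracy_ = acc
            self.n_attempts_ = attempt + 1
            if best is None or acc > best[0]:
                best = (acc, self.net_, self.history_)
            if self.epochs == 0 or acc >= self.stuck_threshold:
                return self
        logger.warning(
            "all %d training attempts stuck below accuracy %.2f; "
            "keeping the best attempt (accuracy %.3f)",
            n_attempts,
            self.stuck_threshold,
            best[0],
        )
        self.final_train_accuracy_, self.net_, self.history_ = best
        return self

    def fine_tuned(
        self,
        X,
        y,
        learning_rate: float | None = None,
        epochs: int | None = None,
        seed: int | None = None,
    ):
        """Return a personalised copy trained further on ``(X, y)``.

        The continuation learning rate (default one tenth of the general
        rate) must be smaller than the rate the general model was trained
        with, so the model is only tweaked; the epoch count defaults to the
        general one — at a 10x smaller rate this still amounts to a tweak,
        but it is enough steps to de-saturate an output that the general
        model got confidently wrong on an atypical subject.  This estimator
        itself is left unmodified.
        """
        if not hasattr(self, "net_"):
            raise ValueError("fine_tuned requires a fitted model")
        lr = 0.1 * self.learning_rate if learning_rate is None else learning_rate
        if epochs is None:
            epochs = self.epochs
        if lr >= self.learning_rate:
            raise ValueError(
                f"fine-tune learning rate ({lr}) must be smaller than the "
                f"general rate ({self.learning_rate})"
            )
        X = self._check_X(X)
        y = np.asarray(y, dtype=int).ravel()
        tuned = copy.deepcopy(self)
        if seed is None:
            seed = self.random_state
        tuned._train_once(
            tuned._transform(X),
            y,
            lr,
            epochs,
            tuned.batch_size,
            _derived_rng(seed, 0, 0x33),
        )
        return tuned

    # inference -------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        X = self._transform(self._check_X(X))
        return self.net_.forward_logits(X, train=False)

    def predict_proba(self, X) -> np.ndarray:
        p1 = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0.0).astype(int)

    @property
    def n_parameters_(self) -> int:
        return self.net_.n_parameters()


class NNGaitClassifier(_BaseGaitClassifier):
    """8 extracted features -> one hidden layer of 4 sigmoid units -> 1 output."""

    def __init__(
        self,
        learning_rate: float = 0.05,
        epochs: int = 150,
        batch_size: int = 32,
        random_state: int = 0,
        stuck_threshold: float = 0.6,
        max_retrains: int = 5,
        standardize: bool = True,
    ):
        super().__init__(
            learning_rate, epochs, batch_size, random_state,
            stuck_threshold, max_retrains,
        )
        self.standardize = standardize

    def _build_network(self) -> Network:
        return Network(
            [Dense(N_FEATURES, 4, activation="sigmoid"), Dense(4, 1)]
        )

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"expected (n, {N_FEATURES}) feature rows, got {X.shape}")
        return X

    def _fit_scaler(self, X: np.ndarray) -> None:
        if self.standardize:
            self.feature_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.feature_scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.feature_mean_ = np.zeros(N_FEATURES)
            self.feature_scale_ = np.ones(N_FEATURES)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "feature_mean_"):
            return X
        return (X - self.feature_mean_) / self.feature_scale_


class CNNGaitClassifier(_BaseGaitClassifier):
    """1-D CNN on raw (200, 3) windows.

    ``wide_second_conv`` switches the second convolution from 8 filters of
    kernel 16 (the default reading of "halving the filter size") to 16
    filters of kernel 32.
    """

    def __init__(
        self,
        learning_rate: float = 0.01,
        epochs: int = 60,
        batch_size: int = 32,
        random_state: int = 0,
        stuck_threshold: float = 0.6,
        max_retrains: int = 5,
        input_len: int = WINDOW_LEN,
        wide_second_conv: bool = False,
    ):
        super().__init__(
            learning_rate, epochs, batch_size, random_state,
            stuck_threshold, max_retrains,
        )
        self.input_len = input_len
        self.wide_second_conv = wide_second_conv

    def _build_network(self) -> Network:
        if self.wide_second_conv:
            conv2 = Conv1D(32, 8, 16, activation="relu")
        else:
            conv2 = Conv1D(16, 8, 8, activation="relu")
        layers = [
            Conv1D(32, 3, 8, activation="relu"),
            MaxPool1D(3),
            Dropout(0.2),
            conv2,
            MaxPool1D(3),
            Dropout(0.2),
            Flatten(),
        ]
        length = self.input_len
        n_ch = 3
        for layer in layers:
            if isinstance(layer, Conv1D):
                length = length - layer.kernel + 1
                n_ch = layer.n_out
            elif isinstance(layer, MaxPool1D):
                length = (length - layer.size) // layer.size + 1
        layers += [Dense(length * n_ch, 3, activation="relu"), Dense(3, 1)]
        return Network(layers)

    _dtype = np.float32

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=self._dtype)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.input_len or X.shape[2] != 3:
            raise ValueError(
                f"expected (n, {self.input_len}, 3) windows, got {X.shape}"
            )
        return X


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimators
# ---------------------------------------------------------------------------

def build_nn(seed: int) -> NNGaitClassifier:
    """A freshly initialised (untrained) feature NN."""
    return NNGaitClassifier(random_state=int(seed)).initialize()


def build_cnn(seed: int, **kwargs) -> CNNGaitClassifier:
    """A freshly initialised (untrained) window CNN."""
    return CNNGaitClassifier(random_state=int(seed), **kwargs).initialize()


def nn_forward(model: NNGaitClassifier, features) -> float | np.ndarray:
    """Gait probability for one 8-feature row (or a batch of rows)."""
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    p = model.predict_proba(features if not single else features[None])[:, 1]
    return float(p[0]) if single else p


def cnn_forward(model: CNNGaitClassifier, window) -> float | np.ndarray:
    """Gait probability for one (200, 3) window (or a batch)."""
    window = np.asarray(window, dtype=float)
    single = window.ndim == 2
    p = model.predict_proba(window if not single else window[None])[:, 1]
    return float(p[0]) if single else p


def train(model, X, y, config: TrainConfig):
    """Continue training a copy of ``model`` under ``config``.

    Returns ``(trained copy, history)``; with ``config.epochs == 0`` the
    copy equals the input model.  Raises on single-class data.
    """
    y = np.asarray(y, dtype=int).ravel()
    if len(y) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    trained = copy.deepcopy(model)
    if not hasattr(trained, "net_"):
        trained.initialize(config.seed)
    X = trained._check_X(X)
    if not hasattr(trained, "feature_mean_"):
        trained._fit_scaler(X)
    hist = trained._train_once(
        trained._transform(X),
        y,
        config.learning_rate,
        config.epochs,
        config.batch_size,
        _derived_rng(config.seed, 0, 0x22),
    )
    return trained, hist


def train_with_retries(build_fn, X, y, config: TrainConfig):
    """Train with the stuck-model rule via a builder.

    ``build_fn(seed)`` must return a fresh untrained estimator; attempt i
    uses a seed derived from ``(config.seed, i)``.  Returns the first model
    whose final training accuracy reaches ``config.stuck_threshold``, else
    the best attempt with a logged warning.
    """
    if config.max_retrains < 1:
        raise ValueError("max_retrains must be at least 1")
    seeds = [
        int(s)
        for s in np.random.SeedSequence([int(config.seed), 0x77]).generate_state(
            config.max_retrains
        )
        % (2**31)
    ]
    best = None
    for attempt_seed in seeds:
        model = build_fn(attempt_seed)
        model, hist = train(
            model, X, y, dataclasses.replace(config, seed=attempt_seed)
        )
        if len(hist["accuracy"]):
            acc = float(hist["accuracy"][-1])
        else:
            Xc = model._check_X(X)
            acc = float(
                np.mean(model.predict(Xc) == np.asarray(y, dtype=int).ravel())
            )
        model.final_train_accuracy_ = acc
        if best is None or acc > best[0]:
            best = (acc, model)
        if acc >= config.stuck_threshold:
            return model
    logger.warning(
        "all %d attempts stuck below accuracy %.2f; keeping best (%.3f)",
        config.max_retrains,
        config.stuck_threshold,
        best[0],
    )
    return best[1]


def count_parameters(model) -> int:
    """Total trainable weight and bias entries of a built model."""
    net = model.net_ if hasattr(model, "net_") else model
    return net.n_parameters()


# ---------------------------------------------------------------------------
# Checkpointing: self-describing JSON, round-trips bit-exactly
# ---------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, numbers.Integral):
        return int(o)
    if isinstance(o, numbers.Real):
        return float(o)
    raise TypeError(type(o))


def save_model(model: _BaseGaitClassifier, path: str | Path) -> None:
    """Serialise architecture + parameters + scaler state to JSON."""
    state = {
        "class": type(model).__name__,
        "params": model.get_params(),
        "weights": [p.tolist() for p in model.net_.parameters()]
        if hasattr(model, "net_")
        else None,
    }
    for attr in ("feature_mean_", "feature_scale_", "final_train_accuracy_"):
        if hasattr(model, attr):
            state[attr] = getattr(model, attr)
    with open(path, "w") as fh:
        json.dump(state, fh, default=_json_default)


def load_model(path: str | Path) -> _BaseGaitClassifier:
    with open(path) as fh:
        state = json.load(fh)
    cls = {"NNGaitClassifier": NNGaitClassifier, "CNNGaitClassifier": CNNGaitClassifier}[
        state["class"]
    ]
    model = cls(**state["params"])
    if state["weights"] is not None:
        model.initialize()
        model.net_.set_parameters([np.asarray(w) for w in state["weights"]])
    for attr in ("feature_mean_", "feature_scale_"):
        if attr in state:
            setattr(model, attr, np.asarray(state[attr]))
    if "final_train_accuracy_" in state:
        model.final_train_accuracy_ = state["final_train_accuracy_"]
    return model
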