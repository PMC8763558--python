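"""Bidirectional gated recurrent classifier, implemented from scratch in numpy.

The recurrent cell follows a nonstandard printed form that mixes GRU and
LSTM conventions (referred to as the *paper-GRU* throughout the code to
avoid confusion with the textbook GRU):

    i   = sigmoid(W_xi x_t + W_hi h_{t-1} + b_i)
    f   = sigmoid(W_xf x_t + W_hf h_{t-1} + b_f)
    g   = tanh   (W_xg x_t + W_hg (i . h_{t-1}) + b_g)
    h_t = (1 - f) . h_{t-1} + f . g

where ``.`` is element-wise multiplication.  One cell reads the sequence
forward, a second reads it backward; the two final hidden states are
concatenated and fed through a linear readout with softmax normalization.
Training minimizes cross-entropy by mini-batch gradient descent with
back-propagation through time, with gradients derived analytically for
exactly the equations above (a central-difference oracle validates them in
the test suite).

Tabular rows enter the recurrence as length-D sequences of scalars (one
feature per time step, ordered by column index), so a subject with D
selected features becomes a D-step sequence with input size 1.  Features
are standardized with statistics fitted on the training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, softmax
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "GRUParams",
    "BiGRUModel",
    "gru_cell_step",
    "bigru_forward",
    "loss_and_grads",
    "train",
    "predict",
    "BiGRUClassifier",
    "bigru_cv_error",
    "save_model",
    "load_model",
]

PARAM_NAMES = ("W_xi", "W_hi", "W_xf", "W_hf", "W_xg", "W_hg", "b_i", "b_f", "b_g")


@dataclass
class GRUParams:
    """Weights and biases of one directional paper-GRU cell."""

    W_xi: np.ndarray
    W_hi: np.ndarray
    W_xf: np.ndarray
    W_hf: np.ndarray
    W_xg: np.ndarray
    W_hg: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_g: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.b_i.size

    @property
    def input_size(self) -> int:
        return self.W_xi.shape[1]

    def validate(self) -> None:
        h, d = self.hidden_size, self.input_size
        for name in ("W_xi", "W_xf", "W_xg"):
            if getattr(self, name).shape != (h, d):
                raise ValueError(f"{name} must have shape ({h}, {d})")
        for name in ("W_hi", "W_hf", "W_hg"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must have shape ({h}, {h})")
        for name in ("b_i", "b_f", "b_g"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have shape ({h},)")

    @classmethod
    def zeros(cls, input_size: int, hidden_size: int) -> "GRUParams":
        h, d = hidden_size, input_size
        shapes = [(h, d), (h, h), (h, d), (h, h), (h, d), (h, h), (h,), (h,), (h,)]
        return cls(*(np.zeros(s) for s in shapes))

    @classmethod
    def random(cls, input_size: int, hidden_size: int, rng: np.random.Generator, scale: float = 0.1) -> "GRUParams":
        p = cls.zeros(input_size, hidden_size)
        for name in PARAM_NAMES:
            arr = getattr(p, name)
            setattr(p, name, rng.uniform(-scale, scale, arr.shape))
        return p


@dataclass
class BiGRUModel:
    """Two directional cells, a linear readout over their concatenation, and labels."""

    forward_cell: GRUParams
    backward_cell: GRUParams
    W_out: np.ndarray  # (n_classes, 2 * hidden)
    b_out: np.ndarray  # (n_classes,)
    classes: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.forward_cell.hidden_size

    @classmethod
    def init(cls, input_size: int, hidden_size: int, classes, rng: np.random.Generator, scale: float = 0.1) -> "BiGRUModel":
        classes = np.asarray(classes)
        return cls(
            forward_cell=GRUParams.random(input_size, hidden_size, rng, scale),
            backward_cell=GRUParams.random(input_size, hidden_size, rng, scale),
            W_out=rng.uniform(-scale, scale, (classes.size, 2 * hidden_size)),
            b_out=rng.uniform(-scale, scale, classes.size),
            classes=classes,
        )


def gru_cell_step(params: GRUParams, x_t: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """One paper-GRU step; accepts a single vector or a batch (rows = samples)."""
    params.validate()
    x_t = np.atleast_2d(x_t)
    h_prev = np.atleast_2d(h_prev)
    if x_t.shape[1] != params.input_size or h_prev.shape[1] != params.hidden_size:
        raise ValueError(
            f"expected input width {params.input_size} and hidden width "
            f"{params.hidden_size}, got {x_t.shape[1]} and {h_prev.shape[1]}"
        )
    h, *_ = _cell_forward(params, x_t, h_prev)
    return h[0] if h.shape[0] == 1 else h


def _cell_forward(params: GRUParams, x_t: np.ndarray, h_prev: np.ndarray):
    i = expit(x_t @ params.W_xi.T + h_prev @ params.W_hi.T + params.b_i)
    f = expit(x_t @ params.W_xf.T + h_prev @ params.W_hf.T + params.b_f)
    r = i * h_prev
    g = np.tanh(x_t @ params.W_xg.T + r @ params.W_hg.T + params.b_g)
    h = (1.0 - f) * h_prev + f * g
    return h, i, f, g, r


def _run_direction(params: GRUParams, X: np.ndarray):
    """Run one cell over a batch of sequences ``X`` of shape (B, T, d).

    Returns the final hidden state and the per-step caches needed by BPTT.
    """
    B, T, _ = X.shape
    h = np.zeros((B, params.hidden_size))
    caches = []
    for t in range(T):
        h_prev = h
        h, i, f, g, r = _cell_forward(params, X[:, t, :], h_prev)
        caches.append((X[:, t, :], h_prev, i, f, g, r))
    return h, caches


def _backprop_direction(params: GRUParams, caches, dh: np.ndarray) -> dict:
    """BPTT through one directional cell given the gradient at its final state."""
    grads = {name: np.zeros_like(getattr(params, name)) for name in PARAM_NAMES}
    for x_t, h_prev, i, f, g, r in reversed(caches):
        df = dh * (g - h_prev)
        da_f = df * f * (1.0 - f)
        dg = dh * f
        da_g = dg * (1.0 - g * g)
        dr = da_g @ params.W_hg
        di = dr * h_prev
        da_i = di * i * (1.0 - i)
        grads["W_xi"] += da_i.T @ x_t
        grads["W_hi"] += da_i.T @ h_prev
        grads["b_i"] += da_i.sum(axis=0)
        grads["W_xf"] += da_f.T @ x_t
        grads["W_hf"] += da_f.T @ h_prev
        grads["b_f"] += da_f.sum(axis=0)
        grads["W_xg"] += da_g.T @ x_t
        grads["W_hg"] += da_g.T @ r
        grads["b_g"] += da_g.sum(axis=0)
        dh = dh * (1.0 - f) + dr * i + da_i @ params.W_hi + da_f @ params.W_hf
    return grads


def _representation(model: BiGRUModel, X: np.ndarray):
    """Concatenated [forward final; backward final] states for a batch (B, T, d)."""
    h_fwd, c_fwd = _run_direction(model.forward_cell, X)
    h_bwd, c_bwd = _run_direction(model.backward_cell, X[:, ::-1, :])
    return np.concatenate([h_fwd, h_bwd], axis=1), c_fwd, c_bwd


def bigru_forward(model: BiGRUModel, sequence: np.ndarray):
    """Forward pass on one sequence (T, d) or a batch (B, T, d).

    Returns ``(representation, class_probabilities)``; the representation
    has width ``2 * hidden_size`` and the probabilities sum to one.
    """
    sequence = np.asarray(sequence, dtype=float)
    single = sequence.ndim == 2
    X = sequence[None] if single else sequence
    if X.ndim != 3 or X.shape[1] < 1:
        raise ValueError("sequence must be (T, d) or (B, T, d) with T >= 1")
    rep, _, _ = _representation(model, X)
    probs = softmax(rep @ model.W_out.T + model.b_out, axis=1)
    if single:
        return rep[0], probs[0]
    return rep, probs


def loss_and_grads(model: BiGRUModel, X: np.ndarray, y_idx: np.ndarray):
    """Mean cross-entropy and analytic gradients for a batch.

    ``X`` is (B, T, d); ``y_idx`` holds class indices into ``model.classes``.
    Gradients are returned as ``{"forward": {...}, "backward": {...},
    "W_out": ..., "b_out": ...}``.
    """
    B = X.shape[0]
    rep, c_fwd, c_bwd = _representation(model, X)
    logits = rep @ model.W_out.T + model.b_out
    probs = softmax(logits, axis=1)
    loss = -np.mean(np.log(probs[np.arange(B), y_idx] + 1e-300))

    dlogits = probs.copy()
    dlogits[np.arange(B), y_idx] -= 1.0
    dlogits /= B
    dW_out = dlogits.T @ rep
    db_out = dlogits.sum(axis=0)
    drep = dlogits @ model.W_out
    H = model.hidden_size
    g_fwd = _backprop_direction(model.forward_cell, c_fwd, drep[:, :H])
    g_bwd = _backprop_direction(model.backward_cell, c_bwd, drep[:, H:])
    return loss, {"forward": g_fwd, "backward": g_bwd, "W_out": dW_out, "b_out": db_out}


def train(
    model: BiGRUModel,
    X: np.ndarray,
    y_idx: np.ndarray,
    *,
    learning_rate: float = 0.05,
    epochs: int = 50,
    batch_size: int = 16,
    seed: int = 0,
):
    """Mini-batch gradient descent on the cross-entropy; returns a per-epoch loss trace.

    The model is updated in place.  Aborts with a diagnostic naming the
    epoch if the loss turns non-finite.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trace = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads = loss_and_grads(model, X[idx], y_idx[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * idx.size
            for name in PARAM_NAMES:
                for cell, g in ((model.forward_cell, grads["forward"]), (model.backward_cell, grads["backward"])):
                    setattr(cell, name, getattr(cell, name) - learning_rate * g[name])
            model.W_out -= learning_rate * grads["W_out"]
            model.b_out -= learning_rate * grads["b_out"]
        trace.append(epoch_loss / n)
    return model, np.asarray(trace)


def predict(model: BiGRUModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels (argmax of class scores, ties to the lower class index)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must be a batch of sequences (B, T, d)")
    if X.shape[2] != model.forward_cell.input_size:
        raise ValueError(
            f"input width {X.shape[2]} does not match the trained width "
            f"{model.forward_cell.input_size}"
        )
    _, probs = bigru_forward(model, X)
    return model.classes[np.argmax(probs, axis=1)]


class BiGRUClassifier:
    """Scikit-learn-style estimator wrapping the bidirectional paper-GRU.

    Each tabular row (n_features,) is standardized with training-set
    statistics and fed as a sequence of scalars.  Deterministic per seed.
    """

    def __init__(
        self,
        hidden_size: int = 8,
        learning_rate: float = 0.05,
        epochs: int = 50,
        batch_size: int = 16,
        init_scale: float = 0.1,
        seed: int = 0,
    ):
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.init_scale = init_scale
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "hidden_size": self.hidden_size,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "init_scale": self.init_scale,
            "seed": self.seed,
        }

    def set_params(self, **kwargs) -> "BiGRUClassifier":
        for k, v in kwargs.items():
            setattr(self, k, v)
        return self

    def _sequence(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self._mean) / self._std
        return Xs[:, :, None]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BiGRUClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self._mean = X.mean(axis=0)
        std = X.std(axis=0)
        self._std = np.where(std > 0, std, 1.0)
        rng = np.random.default_rng(self.seed)
        self.model_ = BiGRUModel.init(1, self.hidden_size, self.classes_, rng, self.init_scale)
        self.model_, self.loss_trace_ = train(
            self.model_,
            self._sequence(X),
            y_idx,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._mean.size:
            raise ValueError(
                f"X has {X.shape[1]} features but the model was fitted with {self._mean.size}"
            )
        return predict(self.model_, self._sequence(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, probs = bigru_forward(self.model_, self._sequence(np.asarray(X, dtype=float)))
        return probs


def save_model(model: BiGRUModel, path, hyperparameters: dict | None = None) -> None:
    """Serialize a model to a single portable JSON file (shape manifest + weights)."""
    import json

    def cell(p: GRUParams) -> dict:
        return {name: getattr(p, name).tolist() for name in PARAM_NAMES}

    payload = {
        "format": "swarmfs-bigru-v1",
        "hidden_size": model.hidden_size,
        "input_size": model.forward_cell.input_size,
        "classes": model.classes.tolist(),
        "hyperparameters": hyperparameters or {},
        "forward": cell(model.forward_cell),
        "backward": cell(model.backward_cell),
        "W_out": model.W_out.tolist(),
        "b_out": model.b_out.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> BiGRUModel:
    """Inverse of :func:`save_model`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "swarmfs-bigru-v1":
        raise ValueError(f"{path} is not a serialized bidirectional GRU model")

    def cell(d: dict) -> GRUParams:
        return GRUParams(**{name: np.asarray(d[name], dtype=float) for name in PARAM_NAMES})

    return BiGRUModel(
        forward_cell=cell(payload["forward"]),
        backward_cell=cell(payload["backward"]),
        W_out=np.asarray(payload["W_out"], dtype=float),
        b_out=np.asarray(payload["b_out"], dtype=float),
        classes=np.asarray(payload["classes"]),
    )


def bigru_cv_error(dataset, mask, hyperparameters: dict, *, folds: int = 3, seed: int = 0) -> float:
    """Stratified CV misclassification rate of a BiGRU on the masked columns."""
    mask = np.asarray(mask).astype(bool)
    X = dataset.X[:, mask]
    y = dataset.y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    wrong = 0
    for k, (tr, te) in enumerate(skf.split(X, y)):
        clf = BiGRUClassifier(seed=seed + k, **{k_: v for k_, v in hyperparameters.items() if k_ != "seed"})
        clf.fit(X[tr], y[tr])
        wrong += int(np.sum(clf.predict(X[te]) != y[te]))
    return wrong / y.size
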