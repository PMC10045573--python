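"""Extreme Learning Machine (ELM) with optional COA-selected input weights.

An ELM is a single-hidden-layer network whose input weights W and biases b
are random and never trained; the hidden activations H[j, i] = g(Wi . Xj + bi)
make the output weights a linear least-squares problem solved in closed form
by the Moore-Penrose pseudoinverse, beta = pinv(H) @ T. With as many hidden
units as samples the network generically interpolates the training targets
exactly. The COA variant treats the flattened (W, b) vector as a search
space in [-1, 1]^(L*(n+1)) and selects the weights minimizing held-out
misclassification, with beta refit in closed form for every candidate.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy.special import expit

from .coa import CoaParams, coa_minimize
from .exceptions import ArgumentError, DomainError, ShapeError, StateError

__all__ = [
    "ELMModel",
    "LabeledSet",
    "hidden_output",
    "elm_train",
    "elm_predict",
    "coa_elm_train",
    "save_model",
    "load_model",
]

ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
}


@dataclass
class ELMModel:
    """Input weights W (L x n), biases b (L,), activation g, output weights beta."""

    W: np.ndarray
    b: np.ndarray
    activation: str = "sigmoid"
    beta: Optional[np.ndarray] = None

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=np.float64))
        self.b = np.asarray(self.b, dtype=np.float64).ravel()
        if self.W.shape[0] != self.b.shape[0]:
            raise ShapeError("W row count must match bias length")
        if self.activation not in ACTIVATIONS:
            raise ArgumentError(
                f"activation must be one of {sorted(ACTIVATIONS)}, got {self.activation!r}"
            )
        if self.beta is not None:
            self.beta = np.atleast_2d(np.asarray(self.beta, dtype=np.float64))
            if not np.all(np.isfinite(self.beta)):
                raise DomainError("beta must be finite")

    @property
    def L(self) -> int:
        return self.W.shape[0]

    @property
    def n_features(self) -> int:
        return self.W.shape[1]


@dataclass
class LabeledSet:
    """Feature matrix X (N x n) and target matrix T (N x m; one column for
    binary {0,1} labels, one-hot for multiclass)."""

    X: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        T = np.asarray(self.T, dtype=np.float64)
        if T.ndim == 1:
            T = T[:, None]
        self.T = T
        if self.X.shape[0] != self.T.shape[0]:
            raise ShapeError("X and T must have the same number of rows")
        if self.X.shape[0] < 1:
            raise DomainError("need at least one sample")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.T))):
            raise DomainError("features and targets must be finite")

    @property
    def labels(self) -> np.ndarray:
        if self.T.shape[1] == 1:
            return (self.T[:, 0] >= 0.5).astype(np.int64)
        return np.argmax(self.T, axis=1)


def hidden_output(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output matrix H with H[j, i] = g(Wi . Xj + bi)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ShapeError(
            f"X has {X.shape[1]} features but the model expects {model.n_features}"
        )
    g = ACTIVATIONS[model.activation]
    return g(X @ model.W.T + model.b)


def _solve_beta(H: np.ndarray, T: np.ndarray, ridge: float) -> np.ndarray:
    if ridge == 0:
        return np.linalg.pinv(H) @ T
    L = H.shape[1]
    return np.linalg.solve(H.T @ H + ridge * np.eye(L), H.T @ T)


def elm_train(
    data: LabeledSet,
    L: int,
    activation: str = "sigmoid",
    seed: int = 0,
    ridge: float = 1e-8,
) -> ELMModel:
    """Random uniform [-1, 1] input weights/biases; beta by Moore-Penrose
    pseudoinverse (ridge=0) or a Tikhonov-stabilized solve (ridge>0)."""
    if L < 1:
        raise ArgumentError("L must be >= 1")
    rng = np.random.default_rng(seed)
    n = data.X.shape[1]
    W = rng.uniform(-1.0, 1.0, size=(L, n))
    b = rng.uniform(-1.0, 1.0, size=L)
    model = ELMModel(W=W, b=b, activation=activation)
    H = hidden_output(model, data.X)
    model.beta = _solve_beta(H, data.T, ridge)
    return model


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Integer labels: argmax over outputs; threshold 0.5 (ties to 1) when m=1."""
    if model.beta is None:
        raise StateError("model has no output weights; train it first")
    out = hidden_output(model, X) @ model.beta
    if out.shape[1] == 1:
        return (out[:, 0] >= 0.5).astype(np.int64)
    return np.argmax(out, axis=1)


def _stratified_split(labels: np.ndarray, val_fraction: float, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Validation indices stratified by class when each class allows it."""
    n = labels.shape[0]
    n_val = max(1, int(round(val_fraction * n)))
    if n_val >= n:
        n_val = n - 1
    val_idx = []
    classes = np.unique(labels)
    for c in classes:
        rows = np.flatnonzero(labels == c)
        rows = rng.permutation(rows)
        take = int(round(val_fraction * rows.size))
        take = min(take, rows.size - 1)
        val_idx.extend(rows[:take].tolist())
    val_idx = np.array(sorted(val_idx), dtype=np.int64)
    # pad/trim to the requested size with unused rows
    if val_idx.size == 0:
        val_idx = np.array([int(rng.integers(n))])
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    if train_idx.size == 0:
        train_idx = val_idx[:1]
        val_idx = val_idx[1:]
    return train_idx, val_idx


def coa_elm_train(
    data: LabeledSet,
    L: int,
    activation: str = "sigmoid",
    coa_params: Optional[CoaParams] = None,
    val_fraction: float = 0.2,
    seed: int = 0,
    ridge: float = 1e-8,
) -> ELMModel:
    """Select ELM input weights/biases with the coot optimizer.

    Candidate fitness = misclassification rate on a stratified held-out
    fraction, with beta computed in closed form on the training fraction.
    The returned model is rebuilt from the best candidate with beta refit on
    all data. A zero COA budget degenerates to a plain seeded ELM.
    """
    if L < 1:
        raise ArgumentError("L must be >= 1")
    n = data.X.shape[1]
    rng = np.random.default_rng(seed)
    train_idx, val_idx = _stratified_split(data.labels, val_fraction, rng)
    Xtr, Ttr = data.X[train_idx], data.T[train_idx]
    Xval = data.X[val_idx]
    yval = data.labels[val_idx]
    dim = L * (n + 1)

    def unpack(vec: np.ndarray) -> ELMModel:
        W = vec[: L * n].reshape(L, n)
        b = vec[L * n :]
        return ELMModel(W=W, b=b, activation=activation)

    def fitness(vec: np.ndarray) -> float:
        model = unpack(vec)
        H = ACTIVATIONS[activation](Xtr @ model.W.T + model.b)
        model.beta = _solve_beta(H, Ttr, ridge)
        pred = elm_predict(model, Xval)
        return float(np.mean(pred != yval))

    if coa_params is None:
        coa_params = CoaParams(bounds=(-1.0, 1.0), seed=seed)
    if coa_params.iter_max == 0:
        return elm_train(data, L, activation=activation, seed=seed, ridge=ridge)
    result = coa_minimize(fitness, coa_params, dim)
    model = unpack(result.gbest)
    H = hidden_output(model, data.X)
    model.beta = _solve_beta(H, data.T, ridge)
    return model


def compare_coa_vs_plain(
    data: LabeledSet,
    L: int = 25,
    activation: str = "sigmoid",
    coa_params: Optional[CoaParams] = None,
    val_fraction: float = 0.2,
    seed: int = 0,
    ridge: float = 1e-8,
) -> Tuple[float, float]:
    """Paired with/without-COA comparison on one stratified validation split.

    Both arms share the split: the plain ELM draws random input weights and
    fits beta on the training fraction; the COA arm selects input weights by
    validation misclassification over the same fraction. Returns
    ``(coa_val_accuracy, plain_val_accuracy)``.
    """
    rng = np.random.default_rng(seed)
    train_idx, val_idx = _stratified_split(data.labels, val_fraction, rng)
    Xtr, Ttr = data.X[train_idx], data.T[train_idx]
    Xval = data.X[val_idx]
    yval = data.labels[val_idx]
    g = ACTIVATIONS[activation]

    def build(W: np.ndarray, b: np.ndarray) -> ELMModel:
        model = ELMModel(W=W, b=b, activation=activation)
        model.beta = _solve_beta(g(Xtr @ model.W.T + model.b), Ttr, ridge)
        return model

    n = data.X.shape[1]
    rng_w = np.random.default_rng(seed)
    plain = build(rng_w.uniform(-1, 1, (L, n)), rng_w.uniform(-1, 1, L))
    plain_acc = float(np.mean(elm_predict(plain, Xval) == yval))

    def fitness(vec: np.ndarray) -> float:
        model = build(vec[: L * n].reshape(L, n), vec[L * n :])
        return float(np.mean(elm_predict(model, Xval) != yval))

    if coa_params is None:
        coa_params = CoaParams(bounds=(-1.0, 1.0), seed=seed)
    result = coa_minimize(fitness, coa_params, L * (n + 1))
    coa = build(result.gbest[: L * n].reshape(L, n), result.gbest[L * n :])
    coa_acc = float(np.mean(elm_predict(coa, Xval) == yval))
    return coa_acc, plain_acc


def save_model(model: ELMModel, path) -> None:
    """Serialize to a single .npz-style archive with a JSON header."""
    path = Path(path)
    header = json.dumps({"activation": model.activation, "L": model.L, "n": model.n_features})
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", header)
        for name, arr in (("W", model.W), ("b", model.b), ("beta", model.beta)):
            if arr is None:
                continue
            with zf.open(f"{name}.npy", "w") as f:
                np.save(f, arr)


def load_model(path) -> ELMModel:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        arrays = {}
        for name in ("W", "b", "beta"):
            try:
                with zf.open(f"{name}.npy") as f:
                    arrays[name] = np.load(f)
            except KeyError:
                arrays[name] = None
    return ELMModel(
        W=arrays["W"], b=arrays["b"], activation=header["activation"], beta=arrays["beta"]
    )
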