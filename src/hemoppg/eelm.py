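"""Extreme learning machine (ELM) regression and its averaging ensemble (EELM).

A single ELM is a one-hidden-layer network whose input weights W and biases b
are drawn once at random and frozen; only the output weights beta are learned,
in closed form, as the minimum-norm least-squares solution

    beta = pinv(H) @ Y,   H[i, j] = g(w_j . x_i + b_j),

with g the activation (sigmoid by default) and pinv the SVD-based Moore-Penrose
pseudoinverse.  Training is non-iterative; the only hyperparameters are the
hidden width K and the activation.

Because a single ELM's output depends on its random initialisation, the
ensemble (EELM) trains P independently initialised members and averages their
predictions, shrinking the initialisation variance roughly as 1/P.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}

DEFAULT_HIDDEN = 20   # hidden nodes per member
DEFAULT_MEMBERS = 200  # ensemble size


def member_seed(base_seed: int, index: int) -> int:
    """Deterministic, platform-stable per-member seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class ELMParams:
    """One trained ELM: frozen hidden layer (W, b) and learned output beta."""

    W: np.ndarray          # (K, n)
    b: np.ndarray          # (K,)
    beta: np.ndarray       # (K, m)
    activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        K, _ = self.W.shape
        if self.b.shape != (K,) or self.beta.shape[0] != K:
            raise ValueError("inconsistent parameter shapes")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta contains non-finite entries")


def _hidden(X: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str) -> np.ndarray:
    return ACTIVATIONS[activation](X @ W.T + b)


def train_elm(
    X: np.ndarray,
    y: np.ndarray,
    K: int = DEFAULT_HIDDEN,
    activation: str = "sigmoid",
    seed: int = 0,
) -> ELMParams:
    """Train one ELM in closed form.

    W and b are i.i.d. Uniform(-1, 1) from the seed (pairs naturally with
    z-scored inputs); beta solves H beta = Y by SVD pseudoinverse with the
    conventional singular-value cutoff (eps * max(N, K) relative), without any
    ridge term.  Deterministic for fixed (X, y, K, activation, seed).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("empty training matrix")
    y = np.asarray(y, dtype=float)
    Y = y.reshape(len(X), -1)
    if K < 1:
        raise ValueError("K must be >= 1")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
        raise ValueError("training data contains non-finite values")

    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(K, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=K)
    H = _hidden(X, W, b, activation)
    beta = np.linalg.pinv(H) @ Y
    return ELMParams(W=W, b=b, beta=beta, activation=activation, seed=seed)


def predict_elm(model: ELMParams, X: np.ndarray) -> np.ndarray:
    """y_hat = g(X W^T + b) beta; returns a 1-D array for scalar targets."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.W.shape[1]:
        raise ValueError(
            f"expected {model.W.shape[1]} input features, got {X.shape[1]}"
        )
    out = _hidden(X, model.W, model.b, model.activation) @ model.beta
    return out[:, 0] if out.shape[1] == 1 else out


@dataclass
class EnsembleModel:
    """P independently initialised ELMs aggregated by the mean.

    Optionally carries the inference-time preprocessing learned on the training
    set: full-matrix standardization statistics and the selected-feature mask
    (applied in that order, mirroring training).
    """

    members: list[ELMParams]
    aggregation: str = "mean"
    feature_mask: np.ndarray | None = None
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.aggregation != "mean":
            raise ValueError("only mean aggregation is supported")
        ref = self.members[0]
        for m in self.members:
            if m.W.shape != ref.W.shape or m.activation != ref.activation:
                raise ValueError("members must share shape and activation")

    @property
    def n_members(self) -> int:
        return len(self.members)

    def prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        if self.feature_mask is not None:
            X = X[:, self.feature_mask]
        return X


def train_eelm(
    X: np.ndarray,
    y: np.ndarray,
    K: int = DEFAULT_HIDDEN,
    P: int = DEFAULT_MEMBERS,
    activation: str = "sigmoid",
    seed: int = 0,
) -> EnsembleModel:
    """Train P ELMs that differ only by their hidden-layer randomness."""
    if P < 1:
        raise ValueError("P must be >= 1")
    members = [
        train_elm(X, y, K=K, activation=activation, seed=member_seed(seed, i))
        for i in range(P)
    ]
    return EnsembleModel(members=members)


def predict_eelm(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the member predictions, per sample."""
    Xp = model.prepare(X)
    preds = [predict_elm(m, Xp) for m in model.members]
    return np.mean(preds, axis=0)


# ---------------------------------------------------------------------------
# Persistence: single .npz archive with a JSON header plus the member arrays.
# ---------------------------------------------------------------------------

def save_model(model: EnsembleModel, path: str | Path) -> None:
    header = {
        "n_members": model.n_members,
        "activation": model.members[0].activation,
        "seeds": [m.seed for m in model.members],
        "aggregation": model.aggregation,
        "has_mask": model.feature_mask is not None,
        "has_standardization": model.feature_mean is not None,
    }
    arrays: dict[str, np.ndarray] = {
        "header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    }
    for i, m in enumerate(model.members):
        arrays[f"W_{i}"] = m.W
        arrays[f"b_{i}"] = m.b
        arrays[f"beta_{i}"] = m.beta
    if model.feature_mask is not None:
        arrays["feature_mask"] = np.asarray(model.feature_mask)
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_scale"] = model.feature_scale
    np.savez(path, **arrays)


def load_model(path: str | Path) -> EnsembleModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        members = [
            ELMParams(
                W=data[f"W_{i}"], b=data[f"b_{i}"], beta=data[f"beta_{i}"],
                activation=header["activation"], seed=header["seeds"][i],
            )
            for i in range(header["n_members"])
        ]
        mask = data["feature_mask"] if header["has_mask"] else None
        mean = data["feature_mean"] if header["has_standardization"] else None
        scale = data["feature_scale"] if header["has_standardization"] else None
    return EnsembleModel(
        members=members, aggregation=header["aggregation"],
        feature_mask=mask, feature_mean=mean, feature_scale=scale,
    )
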