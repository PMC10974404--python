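"""SVR-RFE feature ranking and subset-size choice.

Recursive feature elimination driven by a linear-kernel support vector
regressor: train on the surviving features, score each feature by its squared
weight w_i^2, drop the single least important feature, and record the
cross-validated RMSE of every surviving subset on the way down.  The retained
subset size is the CV-RMSE argmin (ties broken toward the smaller subset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .errors import DegenerateTargetError


@dataclass(frozen=True)
class SelectConfig:
    C: float = 1.0
    epsilon: float = 0.1
    n_folds: int = 5
    seed: int = 0


@dataclass
class RFERanking:
    """Outcome of one RFE run.

    elimination_order: feature indices from first-eliminated to last-eliminated
    (so the last entries are the most important).
    cv_score_by_k: CV RMSE of the surviving subset of each size k = 1..d.
    """

    elimination_order: list[int]
    cv_score_by_k: dict[int, float]

    @property
    def n_features(self) -> int:
        return len(self.elimination_order)

    def top_k(self, k: int) -> list[int]:
        """Indices of the k most important features, original order preserved."""
        if not 1 <= k <= self.n_features:
            raise ValueError(f"k must lie in [1, {self.n_features}]")
        return sorted(self.elimination_order[-k:])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "elimination_order": self.elimination_order,
            "cv_score_by_k": {str(k): v for k, v in self.cv_score_by_k.items()},
            "chosen_k": choose_k(self),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RFERanking":
        payload = json.loads(Path(path).read_text())
        return cls(
            elimination_order=[int(i) for i in payload["elimination_order"]],
            cv_score_by_k={int(k): float(v) for k, v in payload["cv_score_by_k"].items()},
        )


def _cv_rmse(X: np.ndarray, y: np.ndarray, cfg: SelectConfig) -> float:
    """K-fold CV RMSE of the linear SVR on the given feature subset.

    Fold assignment is fixed by the config seed, so every subset size is scored
    on the same partitions.
    """
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    sq_errors = np.empty_like(y, dtype=float)
    for train_idx, test_idx in kf.split(X):
        model = SVR(kernel="linear", C=cfg.C, epsilon=cfg.epsilon)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        sq_errors[test_idx] = (pred - y[test_idx]) ** 2
    return float(np.sqrt(np.mean(sq_errors)))


def svr_rfe(X: np.ndarray, y: np.ndarray, cfg: SelectConfig | None = None) -> RFERanking:
    """Rank all features by recursive elimination under a linear SVR.

    ``X`` is expected to be standardized (weight magnitudes are only comparable
    on a common scale).  Requires n >= 10 samples and a non-constant target.
    """
    cfg = cfg or SelectConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 samples for {cfg.n_folds}-fold RFE, got {n}")
    if d < 1:
        raise ValueError("need at least one feature")
    if np.ptp(y) == 0:
        raise DegenerateTargetError("constant target: feature importance undefined")

    surviving = list(range(d))
    eliminated: list[int] = []
    cv_score_by_k: dict[int, float] = {}
    while surviving:
        k = len(surviving)
        Xs = X[:, surviving]
        cv_score_by_k[k] = _cv_rmse(Xs, y, cfg)
        if k == 1:
            eliminated.append(surviving.pop())
            break
        model = SVR(kernel="linear", C=cfg.C, epsilon=cfg.epsilon)
        model.fit(Xs, y)
        importance = np.ravel(model.coef_) ** 2
        worst = int(np.argmin(importance))  # ties: first (lowest index) removed
        eliminated.append(surviving.pop(worst))
    return RFERanking(elimination_order=eliminated, cv_score_by_k=cv_score_by_k)


def choose_k(ranking: RFERanking) -> int:
    """Subset size minimising CV RMSE; ties resolved toward the smaller size."""
    best_k, best_score = None, np.inf
    for k in sorted(ranking.cv_score_by_k):
        score = ranking.cv_score_by_k[k]
        if score < best_score:
            best_k, best_score = k, score
    assert best_k is not None
    return best_k


def apply_selection(X: np.ndarray, ranking: RFERanking, k: int) -> np.ndarray:
    """Keep the top-k most important columns, preserving original column order."""
    return np.asarray(X)[:, ranking.top_k(k)]
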