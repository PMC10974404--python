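"""Evaluation protocol: repeated random splits, agreement statistics, error grid.

The protocol mirrors a clinical validation: the cohort is randomly split 8:2
into training and test sets, the model is trained and scored on the test set,
and the whole procedure is repeated (200 times by default) with fresh random
splits; reported metrics are the averages over repeats.  Agreement between the
estimated and reference hemoglobin is summarised by RMSE, the Pearson
correlation (with its two-sided p-value), Bland-Altman limits of agreement
(mean difference +/- 1.96 SD), and a Clarke-style error grid adapted to
hemoglobin: region A |error| <= 1 g/dL (clinically safe), region B
1 < |error| <= 2 g/dL (tolerable), region C |error| > 2 g/dL (risk of
inappropriate treatment).  Boundaries are closed on the safe side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .eelm import predict_eelm, train_eelm
from .errors import HemoppgError
from .features import Standardizer
from .selection import SelectConfig, RFERanking, apply_selection, choose_k, svr_rfe

logger = logging.getLogger(__name__)

BASELINE_MODELS = ("eelm", "elm", "linear", "svr", "rf", "oracle")


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    frac_within: float


@dataclass
class EvaluationReport:
    rmse: float
    pcc: float
    pcc_p: float
    bland_altman: BlandAltman
    grid: tuple[float, float, float]  # percentages in regions A, B, C
    n_repeats: int
    n_skipped: int = 0
    per_repeat: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "rmse": self.rmse,
            "pcc": self.pcc,
            "pcc_p": self.pcc_p,
            "bland_altman": asdict(self.bland_altman),
            "grid": {"pct_A": self.grid[0], "pct_B": self.grid[1], "pct_C": self.grid[2]},
            "n_repeats": self.n_repeats,
            "n_skipped": self.n_skipped,
        }
        return d


def split_dataset(records, train_ratio: float = 0.8, seed: int = 0):
    """Seeded random partition into (train, test); train gets floor(ratio*n)."""
    if not 0 < train_ratio < 1:
        raise ValueError("train_ratio must lie strictly between 0 and 1")
    n = len(records)
    idx_train, idx_test = split_indices(n, train_ratio, seed)
    if isinstance(records, np.ndarray):
        return records[idx_train], records[idx_test]
    return [records[i] for i in idx_train], [records[i] for i in idx_test]


def split_indices(n: int, train_ratio: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_ratio * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def rmse(y_ref, y_pred) -> float:
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_pred - y_ref) ** 2)))


def pcc(y_ref, y_pred) -> tuple[float, float]:
    """Pearson r with its two-sided p-value (t transform, n-2 df)."""
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_ref.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(y_ref) == 0 or np.ptp(y_pred) == 0:
        raise HemoppgError("zero variance: correlation undefined")
    r, p = stats.pearsonr(y_ref, y_pred)
    return float(r), float(p)


def bland_altman(y_ref, y_pred) -> BlandAltman:
    """Agreement statistics of d = pred - ref with 95% limits mean +/- 1.96 SD."""
    d = np.asarray(y_pred, dtype=float) - np.asarray(y_ref, dtype=float)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi,
                       frac_within=within)


def error_grid(y_ref, y_pred) -> tuple[tuple[float, float, float], np.ndarray]:
    """Hemoglobin error-grid percentages (A, B, C) and per-point labels.

    A: |e| <= 1 g/dL; B: 1 < |e| <= 2; C: |e| > 2.  Every point gets exactly
    one label; the boundaries belong to the safer region.
    """
    e = np.abs(np.asarray(y_pred, dtype=float) - np.asarray(y_ref, dtype=float))
    labels = np.where(e <= 1.0, "A", np.where(e <= 2.0, "B", "C"))
    n = e.size
    pct = tuple(float(100.0 * np.sum(labels == z) / n) for z in ("A", "B", "C"))
    return pct, labels


def _fit_predict_baseline(model_name, X_train, y_train, X_test, y_test,
                          K, P, activation, seed):
    """Train the requested regressor and predict the test set.

    The non-EELM entries are comparison hooks (default library settings, not
    tuned replicas); 'oracle' returns the reference values and exists for
    harness self-tests.
    """
    if model_name == "eelm":
        model = train_eelm(X_train, y_train, K=K, P=P, activation=activation, seed=seed)
        return predict_eelm(model, X_test)
    if model_name == "elm":
        from .eelm import predict_elm, train_elm
        return predict_elm(train_elm(X_train, y_train, K=K, activation=activation,
                                     seed=seed), X_test)
    if model_name == "linear":
        from sklearn.linear_model import LinearRegression
        return LinearRegression().fit(X_train, y_train).predict(X_test)
    if model_name == "svr":
        from sklearn.svm import SVR
        return SVR().fit(X_train, y_train).predict(X_test)
    if model_name == "rf":
        from sklearn.ensemble import RandomForestRegressor
        return RandomForestRegressor(random_state=seed).fit(
            X_train, y_train).predict(X_test)
    if model_name == "oracle":
        return np.asarray(y_test, dtype=float).copy()
    raise ValueError(f"unknown model {model_name!r}; choose from {BASELINE_MODELS}")


def repeated_evaluation(
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 200,
    train_ratio: float = 0.8,
    seed: int = 0,
    model: str = "eelm",
    K: int = 20,
    P: int = 200,
    activation: str = "sigmoid",
    select_cfg: SelectConfig | None = None,
    n_features: int | None = None,
    per_repeat_selection: bool = False,
    keep_per_repeat: bool = False,
) -> EvaluationReport:
    """Average metrics over repeated random splits.

    Each repeat: fresh 8:2 split, standardize on the training rows, apply
    feature selection, train, predict the held-out rows, score.  When
    ``select_cfg`` is given, the SVR-RFE ranking is computed on the first
    repeat's training split and the resulting mask reused (set
    ``per_repeat_selection`` to re-rank every repeat); ``n_features`` overrides
    the CV-chosen subset size.  Repeats whose test target is degenerate are
    skipped with a warning and counted in ``n_skipped``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    mask: np.ndarray | None = None
    metrics: dict[str, list] = {k: [] for k in
                                ("rmse", "pcc", "pcc_p", "mean_diff", "sd_diff",
                                 "frac_within", "pct_a", "pct_b", "pct_c")}
    n_skipped = 0
    for rep in range(n_repeats):
        rep_seed = int(np.random.SeedSequence(entropy=seed,
                                              spawn_key=(rep,)).generate_state(1)[0])
        idx_tr, idx_te = split_indices(len(y), train_ratio, rep_seed)
        y_tr, y_te = y[idx_tr], y[idx_te]
        if np.ptp(y_te) == 0 or np.ptp(y_tr) == 0 or y_te.size < 3:
            logger.warning("repeat %d skipped: degenerate split target", rep)
            n_skipped += 1
            continue

        std = Standardizer().fit(X[idx_tr])
        X_tr, X_te = std.transform(X[idx_tr]), std.transform(X[idx_te])

        if select_cfg is not None and (mask is None or per_repeat_selection):
            ranking = svr_rfe(X_tr, y_tr, select_cfg)
            k = n_features if n_features is not None else choose_k(ranking)
            mask = np.array(ranking.top_k(k))
        if mask is not None:
            X_tr, X_te = X_tr[:, mask], X_te[:, mask]

        pred = _fit_predict_baseline(model, X_tr, y_tr, X_te, y_te,
                                     K, P, activation, rep_seed)
        ba = bland_altman(y_te, pred)
        grid, _ = error_grid(y_te, pred)
        r, p = pcc(y_te, pred)
        metrics["rmse"].append(rmse(y_te, pred))
        metrics["pcc"].append(r)
        metrics["pcc_p"].append(p)
        metrics["mean_diff"].append(ba.mean_diff)
        metrics["sd_diff"].append(ba.sd_diff)
        metrics["frac_within"].append(ba.frac_within)
        metrics["pct_a"].append(grid[0])
        metrics["pct_b"].append(grid[1])
        metrics["pct_c"].append(grid[2])

    if not metrics["rmse"]:
        raise HemoppgError("every repeat was skipped; nothing to report")

    mean = {k: float(np.mean(v)) for k, v in metrics.items()}
    loa_lo = mean["mean_diff"] - 1.96 * mean["sd_diff"]
    loa_hi = mean["mean_diff"] + 1.96 * mean["sd_diff"]
    report = EvaluationReport(
        rmse=mean["rmse"],
        pcc=mean["pcc"],
        pcc_p=mean["pcc_p"],
        bland_altman=BlandAltman(mean["mean_diff"], mean["sd_diff"],
                                 loa_lo, loa_hi, frac_within=mean["frac_within"]),
        grid=(mean["pct_a"], mean["pct_b"], mean["pct_c"]),
        n_repeats=n_repeats - n_skipped,
        n_skipped=n_skipped,
        per_repeat={k: list(map(float, v)) for k, v in metrics.items()}
        if keep_per_repeat else None,
    )
    return report
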