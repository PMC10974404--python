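"""Experiment orchestration: config, provenance, and the end-to-end run.

``run_experiment`` ties the stages together: synthesize (or load) a cohort,
preprocess and featurize every subject, rank features by SVR-RFE, run the
repeated split/train/test protocol with the ensemble ELM, and write all
artifacts (feature table, ranking, final model, JSON report) to an output
directory.  Reruns with the same config produce identical reports: every
source of randomness fans out deterministically from the single experiment
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort_io import read_cohort, write_cohort
from .eelm import train_eelm
from .errors import ConfigError
from .evaluate import EvaluationReport, repeated_evaluation, split_indices
from .features import Standardizer, feature_table
from .preprocess import PreprocessConfig
from .selection import SelectConfig, choose_k, svr_rfe
from .synth import ClinicalHbSampler, NoiseConfig, PointMass, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcquisitionConfig:
    fs: float = 100.0
    duration: float = 120.0


@dataclass(frozen=True)
class CohortConfig:
    n: int = 249
    sampler: str = "clinical"      # "clinical" or "point"
    point_value: float = 14.0


@dataclass(frozen=True)
class FeatureConfig:
    win_len: float = 5.0


@dataclass(frozen=True)
class SelectionConfig:
    enabled: bool = True
    C: float = 1.0
    epsilon: float = 0.1
    n_folds: int = 5
    n_features: int | None = None  # None = CV-chosen subset size
    per_repeat: bool = False


@dataclass(frozen=True)
class ModelConfig:
    hidden_nodes: int = 20
    members: int = 200
    activation: str = "sigmoid"


@dataclass(frozen=True)
class EvaluationConfig:
    train_ratio: float = 0.8
    n_repeats: int = 200
    model: str = "eelm"


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)


_SECTION_TYPES = {
    "acquisition": AcquisitionConfig,
    "cohort": CohortConfig,
    "noise": NoiseConfig,
    "preprocess": PreprocessConfig,
    "features": FeatureConfig,
    "selection": SelectionConfig,
    "model": ModelConfig,
    "evaluation": EvaluationConfig,
}


def _build_section(cls, payload: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    for key in payload:
        if key not in names:
            raise ConfigError(f"unknown config key {context}.{key}")
    # YAML reads tuples back as lists; dataclasses with tuple fields accept them.
    payload = {k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()}
    return cls(**payload)


def config_from_dict(payload: dict) -> ExperimentConfig:
    """Validated construction; unknown keys raise ConfigError naming the key."""
    payload = dict(payload or {})
    kwargs = {}
    if "seed" in payload:
        kwargs["seed"] = int(payload.pop("seed"))
    for name, cls in _SECTION_TYPES.items():
        if name in payload:
            section = payload.pop(name)
            if not isinstance(section, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    if payload:
        raise ConfigError(f"unknown config key {sorted(payload)[0]}")
    return ExperimentConfig(**kwargs)


def config_to_dict(cfg: ExperimentConfig) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path: str | Path) -> ExperimentConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def config_hash(cfg: ExperimentConfig) -> str:
    canonical = json.dumps(config_to_dict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _make_sampler(cc: CohortConfig):
    if cc.sampler == "clinical":
        return ClinicalHbSampler()
    if cc.sampler == "point":
        return PointMass(cc.point_value)
    raise ConfigError(f"unknown config key cohort.sampler value {cc.sampler!r}")


def run_experiment(
    cfg: ExperimentConfig,
    outdir: str | Path,
    cohort_dir: str | Path | None = None,
    save_signals: bool = False,
) -> EvaluationReport:
    """Execute the full experiment and write artifacts under ``outdir``.

    When ``cohort_dir`` is given the cohort is loaded from disk instead of
    synthesized.  Artifacts: features.csv, ranking.json (when selection is
    enabled), model.npz (final model trained on all subjects), report.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cohort_dir is not None:
        logger.info("loading cohort from %s", cohort_dir)
        records = read_cohort(cohort_dir)
    else:
        logger.info("synthesizing cohort: n=%d seed=%d", cfg.cohort.n, cfg.seed)
        records = generate_cohort(
            cfg.cohort.n, hb_sampler=_make_sampler(cfg.cohort),
            noise=cfg.noise, seed=cfg.seed,
            duration=cfg.acquisition.duration, fs=cfg.acquisition.fs,
        )
        if save_signals:
            write_cohort(records, outdir / "cohort")

    logger.info("extracting features: window=%gs", cfg.features.win_len)
    table = feature_table(records, cfg.preprocess, cfg.features.win_len)
    table.to_csv(outdir / "features.csv")
    X = table.drop(columns="hb_ref").to_numpy()
    y = table["hb_ref"].to_numpy()

    select_cfg = None
    mask = None
    n_features = None
    if cfg.selection.enabled:
        select_cfg = SelectConfig(C=cfg.selection.C, epsilon=cfg.selection.epsilon,
                                  n_folds=cfg.selection.n_folds, seed=cfg.seed)
        # Rank on the first repeat's training split (the mask reused by the
        # repeated protocol below) and persist it for inspection.
        first_seed = int(np.random.SeedSequence(entropy=cfg.seed,
                                                spawn_key=(0,)).generate_state(1)[0])
        idx_tr, _ = split_indices(len(y), cfg.evaluation.train_ratio, first_seed)
        std = Standardizer().fit(X[idx_tr])
        ranking = svr_rfe(std.transform(X[idx_tr]), y[idx_tr], select_cfg)
        n_features = cfg.selection.n_features or choose_k(ranking)
        ranking.to_json(outdir / "ranking.json")
        mask = np.array(ranking.top_k(n_features))
        logger.info("SVR-RFE kept %d of %d features", n_features, X.shape[1])

    logger.info("repeated evaluation: %d repeats, model=%s",
                cfg.evaluation.n_repeats, cfg.evaluation.model)
    report = repeated_evaluation(
        X, y,
        n_repeats=cfg.evaluation.n_repeats,
        train_ratio=cfg.evaluation.train_ratio,
        seed=cfg.seed,
        model=cfg.evaluation.model,
        K=cfg.model.hidden_nodes,
        P=cfg.model.members,
        activation=cfg.model.activation,
        select_cfg=select_cfg,
        n_features=n_features,
        per_repeat_selection=cfg.selection.per_repeat,
    )

    # Final deployable model: trained on every subject.
    std_all = Standardizer().fit(X)
    X_all = std_all.transform(X)
    if mask is not None:
        X_all = X_all[:, mask]
    final = train_eelm(X_all, y, K=cfg.model.hidden_nodes, P=cfg.model.members,
                       activation=cfg.model.activation, seed=cfg.seed)
    final.feature_mask = mask
    final.feature_mean = std_all.mean_
    final.feature_scale = std_all.scale_
    from .eelm import save_model
    save_model(final, outdir / "model.npz")

    n_train = int(np.floor(cfg.evaluation.train_ratio * len(y)))
    payload = {
        "report": report.to_dict(),
        "provenance": {
            "package_version": __version__,
            "config_hash": config_hash(cfg),
            "seed": cfg.seed,
            "n_subjects": int(len(y)),
            "n_dropped_records": int(table.attrs.get("n_dropped", 0)),
            "split_sizes": {"train": n_train, "test": int(len(y) - n_train)},
            "selected_features": int(n_features) if n_features else None,
        },
        "config": config_to_dict(cfg),
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, default=list))
    logger.info("experiment complete: RMSE=%.3f g/dL, PCC=%.3f",
                report.rmse, report.pcc)
    return report
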