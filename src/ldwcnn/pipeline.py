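"""End-to-end orchestration: preprocess -> normalize -> split -> LDA -> GWO
-> CNN -> classify -> severity recommendation -> metrics.

Stages run in a fixed order with per-stage logging; disabling a stage
(``select_iterations=0`` / ``tune_iterations=0`` / the CNN-only baseline
variant) bypasses it without reordering the others.  Every random choice is
driven by a seed named in the config, so identical configs reproduce
identical reports bit-for-bit in single-threaded execution.

GWO is used in two sequential passes: wrapper feature selection on a fixed
default CNN first, then hyperparameter tuning (log-scale learning rate and
dropout) on the selected features.  Both passes train reduced-epoch CNNs as
their fitness evaluators to keep the wrapper affordable on desk-size data.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical_io import ClinicalTable, SplitBundle, impute, normalize, stratified_split
from .cnn import (CNNSpec, TrainedClassifier, build, default_grid_shape,
                  predict_proba, train)
from .evaluation import MetricsReport, kfold_cv, metrics_from_predictions
from .gwo import FeatureMask, GWOConfig, ParamRange, select_features, tune_hyperparameters
from .lda import LDAModel, fit_lda, project
from .recommend import (Recommendation, RiskFlags, SeverityAssessment,
                        band_heart, band_kidney, band_liver, recommend,
                        severity_level)
from .synthdata import SchemaSpec, generate, make_schema_preset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run; round-trips through YAML."""

    schema: str = "liver"
    five_class: bool = False
    source_path: str | None = None   # read this file instead of simulating
    # synthetic-data stage
    n: int = 600
    effect_size: float = 1.0
    missing_rate: float = 0.05
    data_seed: int = 0
    # preprocessing
    impute_strategy: str = "impute"
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    # LDA
    lda_k: int | None = None         # None -> min(d, C-1)
    lda_ridge: float | None = None   # None -> 1e-6 trace(S_w)/d
    # GWO feature selection
    select_wolves: int = 5
    select_iterations: int = 5
    lambda_sparsity: float = 0.01
    selection_epochs: int = 10
    # GWO hyperparameter tuning
    tune_wolves: int = 4
    tune_iterations: int = 3
    tuning_epochs: int = 15
    gwo_seed: int = 0
    # CNN
    cnn_overrides: dict = field(default_factory=dict)
    train_seed: int = 0
    # cross-validation harness
    cv: bool = False
    cv_k: int = 10
    # output
    output_dir: str | None = None
    variant: str = "ldw_cnn"  # or "cnn_baseline"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ratios"] = list(self.ratios)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["ratios"] = tuple(d.get("ratios", (0.6, 0.2, 0.2)))
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    variant: str
    dataset_id: str
    selected_mask: list[int]
    tuned_spec: CNNSpec
    metrics: MetricsReport
    assessments: list[SeverityAssessment]
    recommendations: list[Recommendation]
    cv_summary: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "dataset_id": self.dataset_id,
            "selected_mask": self.selected_mask,
            "tuned_spec": self.tuned_spec.to_dict(),
            "metrics": self.metrics.to_dict(),
            "recommendations": [
                {"disease": a.disease, "probability": a.probability,
                 "risk_boost": a.risk_boost, "level": a.level,
                 "tier": r.tier, "message": r.message}
                for a, r in zip(self.assessments, self.recommendations)],
            "cv_summary": self.cv_summary,
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


class DiseaseModelRegistry:
    """Thin dispatcher: one trained model per disease dataset, routed by
    the table's declared dataset_id."""

    def __init__(self) -> None:
        self._models: dict[str, TrainedClassifier] = {}

    def register(self, dataset_id: str, clf: TrainedClassifier) -> None:
        self._models[dataset_id] = clf

    def classify(self, dataset_id: str, X: np.ndarray) -> np.ndarray:
        if dataset_id not in self._models:
            raise KeyError(f"no model registered for dataset {dataset_id!r}")
        return predict_proba(self._models[dataset_id], X)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _load_stage(config: PipelineConfig) -> tuple[SchemaSpec, ClinicalTable]:
    schema = make_schema_preset(config.schema, five_class=config.five_class)
    if config.source_path:
        from .clinical_io import read_table
        table = read_table(config.source_path, schema)
    else:
        table = generate(schema, config.n, config.effect_size,
                         config.missing_rate, config.data_seed)
    logger.info("stage load: %d rows, %d features (%s)", table.n_rows,
                len(table.feature_meta), table.dataset_id)
    return schema, table


def _impute_with_train_stats(train: ClinicalTable, others: list[ClinicalTable],
                             strategy: str) -> list[ClinicalTable]:
    """Fill missing slots everywhere using training-split statistics."""
    if strategy == "drop_rows":
        return [impute(t, "drop_rows") for t in [train] + others]
    filled_train = impute(train, "impute")
    out = [filled_train]
    for t in others:
        data = t.data.copy()
        for m in t.feature_meta:
            if not data[m.name].isna().any():
                continue
            ref = filled_train.data[m.name]
            fill = float(ref.mean()) if m.kind == "continuous" else ref.mode().iloc[0]
            data[m.name] = data[m.name].fillna(fill)
        out.append(ClinicalTable(data, t.feature_meta, t.labels.copy(),
                                 t.label_set, t.dataset_id))
    return out


def _quick_spec(base: CNNSpec, epochs: int) -> CNNSpec:
    return replace(base, epochs=epochs, patience=3)


def _train_eval(spec: CNNSpec, Xtr, ytr, Xva, yva, seed: int) -> float:
    """Validation accuracy of a freshly built and trained candidate."""
    model = build(spec)
    clf = train(model, (Xtr, ytr), (Xva, yva), spec, seed=seed)
    proba = predict_proba(clf, Xva)
    return float(np.mean(proba.argmax(axis=1) == yva))


def _extract_flags(raw_row: pd.Series, dataset_id: str) -> RiskFlags | None:
    """Reference-range flags from raw (pre-normalisation) marker values.

    Markers without a column in the schema are skipped; a dataset with no
    banded markers yields None (zero risk boost).  The heart schema carries
    only systolic pressure, so the diastolic slot is held at its normal
    reference value; the kidney schema carries no sex column, so the wider
    male creatinine range is applied.
    """
    try:
        if dataset_id == "liver" and {"sgot", "sgpt"} <= set(raw_row.index):
            return band_liver(max(float(raw_row["sgot"]), 0.0),
                              max(float(raw_row["sgpt"]), 0.0))
        if dataset_id == "kidney" and {"sc", "pot"} <= set(raw_row.index):
            return band_kidney(max(float(raw_row["sc"]), 0.0),
                               max(float(raw_row["pot"]), 0.0), "male")
        if dataset_id == "heart" and {"trestbps", "chol"} <= set(raw_row.index):
            return band_heart(max(float(raw_row["trestbps"]), 0.0), 80.0,
                              max(float(raw_row["chol"]), 0.0))
    except (TypeError, ValueError):
        logger.warning("could not band markers for a %s row", dataset_id)
    return None


class StageError(RuntimeError):
    """Raised with the stage name when a stage fails."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _fit_features(config: PipelineConfig, bundle: SplitBundle
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, LDAModel | None]:
    """Normalised (and for the full variant LDA-projected) feature matrices."""
    _, (ntr, nva, nte) = normalize(bundle.train, [bundle.validation, bundle.test])
    Xtr, Xva, Xte = ntr.to_matrix(), nva.to_matrix(), nte.to_matrix()
    if config.variant == "cnn_baseline":
        return Xtr, Xva, Xte, None
    C = len(bundle.train.label_set)
    k = config.lda_k or min(Xtr.shape[1], C - 1)
    model = fit_lda(ntr, K=k, ridge=config.lda_ridge)
    return project(model, Xtr), project(model, Xva), project(model, Xte), model


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full hybrid run and return (and optionally write) the
    report.  Any stage error aborts with the stage name attached."""
    stage = "load"
    try:
        schema, table = _load_stage(config)

        stage = "split"
        bundle = stratified_split(table, config.ratios, config.split_seed)

        stage = "impute"
        tr, va, te = _impute_with_train_stats(
            bundle.train, [bundle.validation, bundle.test], config.impute_strategy)
        bundle = SplitBundle(tr, va, te, bundle.ratios, bundle.seed)
        raw_test = te  # pre-normalisation values for reference-range banding

        stage = "normalize+lda"
        Xtr, Xva, Xte, lda_model = _fit_features(config, bundle)
        ytr, yva, yte = tr.labels, va.labels, te.labels
        n_classes = len(table.label_set)
        dim = Xtr.shape[1]
        logger.info("stage features: %d dims (%s)", dim, config.variant)

        stage = "gwo_select"
        do_gwo = config.variant != "cnn_baseline"
        if do_gwo and config.select_iterations > 0 and dim > 1:
            base = CNNSpec(grid_shape=default_grid_shape(dim), n_classes=n_classes,
                           init_seed=config.train_seed, **config.cnn_overrides)

            def sel_evaluator(mask: FeatureMask) -> float:
                cols = mask.indices
                spec = replace(_quick_spec(base, config.selection_epochs),
                               grid_shape=default_grid_shape(len(cols)))
                acc = _train_eval(spec, Xtr[:, cols], ytr, Xva[:, cols], yva,
                                  seed=config.train_seed)
                return 1.0 - acc

            mask = select_features(sel_evaluator, dim,
                                   GWOConfig(n_wolves=config.select_wolves,
                                             iterations=config.select_iterations,
                                             seed=config.gwo_seed,
                                             lambda_sparsity=config.lambda_sparsity))
        else:
            mask = FeatureMask(np.ones(dim, dtype=bool))
        cols = mask.indices
        Xtr, Xva, Xte = Xtr[:, cols], Xva[:, cols], Xte[:, cols]
        logger.info("stage gwo_select: kept %d/%d dims", len(cols), dim)

        stage = "gwo_tune"
        grid = default_grid_shape(Xtr.shape[1])
        base_spec = CNNSpec(grid_shape=grid, n_classes=n_classes,
                            init_seed=config.train_seed, **config.cnn_overrides)
        if do_gwo and config.tune_iterations > 0:
            space = {
                "learning_rate": ParamRange(1e-4, 1e-2, log=True),
                "dropout_rate": ParamRange(0.2, 0.7),
            }

            def tune_evaluator(spec: CNNSpec) -> float:
                return _train_eval(_quick_spec(spec, config.tuning_epochs),
                                   Xtr, ytr, Xva, yva, seed=config.train_seed)

            tuned = tune_hyperparameters(space, tune_evaluator,
                                         GWOConfig(n_wolves=config.tune_wolves,
                                                   iterations=config.tune_iterations,
                                                   seed=config.gwo_seed + 1),
                                         base_spec=base_spec)
            tuned = replace(tuned, epochs=base_spec.epochs, patience=base_spec.patience)
        else:
            tuned = base_spec

        stage = "train"
        clf = train(build(tuned), (Xtr, ytr), (Xva, yva), tuned,
                    seed=config.train_seed)

        stage = "classify"
        proba = predict_proba(clf, Xte)
        y_pred = proba.argmax(axis=1)
        metrics = metrics_from_predictions(yte, y_pred, proba, n_classes)

        stage = "recommend"
        assessments, recs = [], []
        positive_prob = 1.0 - proba[:, 0]  # class 0 is the no/least-severe class
        for i in range(len(yte)):
            disease = table.dataset_id if y_pred[i] != 0 else "none"
            flags = _extract_flags(raw_test.data.iloc[i], table.dataset_id)
            a = severity_level(float(positive_prob[i]), flags, disease)
            assessments.append(a)
            recs.append(recommend(a.level, disease))

        stage = "cv"
        cv_summary = None
        if config.cv:
            _, summary = kfold_cv(fold_runner(config), table, config.cv_k,
                                  seed=config.split_seed)
            cv_summary = {k: list(v) for k, v in summary.items()}
    except StageError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    report = PipelineReport(
        variant=config.variant, dataset_id=table.dataset_id,
        selected_mask=mask.bits.astype(int).tolist(), tuned_spec=tuned,
        metrics=metrics, assessments=assessments, recommendations=recs,
        cv_summary=cv_summary,
        provenance={"config": config.to_dict(), "config_hash": config.hash(),
                    "package_version": __version__,
                    "seeds": {"data": config.data_seed, "split": config.split_seed,
                              "gwo": config.gwo_seed, "train": config.train_seed}})
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out / "report.json")
        with open(out / "recommendations.jsonl", "w") as fh:
            for i, (a, r) in enumerate(zip(assessments, recs)):
                fh.write(json.dumps({"id": i, "disease": a.disease,
                                     "level": a.level, "tier": r.tier,
                                     "message": r.message}) + "\n")
    return report


def run_baseline_cnn(config: PipelineConfig) -> PipelineReport:
    """Same flow with LDA and GWO disabled: raw normalised features into the
    CNN.  Enables the CNN-vs-hybrid comparison on matched data and seeds."""
    return run_pipeline(replace(config, variant="cnn_baseline"))


def fold_runner(config: PipelineConfig
                ) -> Callable[[ClinicalTable, ClinicalTable],
                              tuple[np.ndarray, np.ndarray]]:
    """Adapter for k-fold CV: re-fits all preprocessing (imputation stats,
    normalisation, LDA) inside each training fold to avoid leakage."""

    def run(train_table: ClinicalTable, test_table: ClinicalTable
            ) -> tuple[np.ndarray, np.ndarray]:
        inner = stratified_split(train_table, (0.75, 0.25, 0.0),
                                 seed=config.split_seed)
        tr, va, te = _impute_with_train_stats(
            inner.train, [inner.validation, test_table], config.impute_strategy)
        bundle = SplitBundle(tr, va, te, inner.ratios, inner.seed)
        Xtr, Xva, Xte, _ = _fit_features(config, bundle)
        n_classes = len(train_table.label_set)
        spec = CNNSpec(grid_shape=default_grid_shape(Xtr.shape[1]),
                       n_classes=n_classes, init_seed=config.train_seed,
                       **config.cnn_overrides)
        clf = train(build(spec), (Xtr, tr.labels), (Xva, va.labels), spec,
                    seed=config.train_seed)
        proba = predict_proba(clf, Xte)
        return proba.argmax(axis=1), proba

    return run
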