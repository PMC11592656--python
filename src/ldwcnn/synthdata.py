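"""Synthetic clinical tables with the statistical structure the pipeline assumes.

Each schema preset (``heart``, ``liver``, ``kidney``) mirrors the attribute
list of the corresponding public UCI clinical dataset and draws features
class-conditionally: continuous markers from Gaussians whose between-class
mean separation is scaled by an effect size ``d`` (``d = 0`` makes the class
distributions identical), categorical markers from per-class category
probabilities whose log-odds shifts are scaled the same way.  Missingness is
injected completely at random.  Continuous baselines for markers with
published reference ranges (AST/ALT, serum creatinine, potassium, blood
pressure, cholesterol) are centred on the normal band so that downstream
risk flagging sees realistic healthy values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .clinical_io import CATEGORICAL, CONTINUOUS, ClinicalTable, FeatureMeta


@dataclass(frozen=True)
class ContinuousGen:
    """Class-conditional Gaussian: mean + d * class_shift[k] * sd, spread sd."""

    mean: float
    sd: float
    class_shift: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be strictly positive")


@dataclass(frozen=True)
class CategoricalGen:
    """Per-class category probabilities via d-scaled log-odds shifts."""

    categories: tuple[str, ...]
    base_probs: tuple[float, ...]
    class_logit_shift: tuple[tuple[float, ...], ...]  # [class][category]

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if any(p <= 0 for p in self.base_probs):
            raise ValueError("base_probs must be strictly positive")

    def probs(self, k: int, d: float) -> np.ndarray:
        logit = np.log(self.base_probs) + d * np.asarray(self.class_logit_shift[k])
        e = np.exp(logit - logit.max())
        return e / e.sum()


@dataclass(frozen=True)
class SchemaSpec:
    """Dataset schema: feature metadata plus class-conditional generators."""

    dataset_id: str
    feature_meta: tuple[FeatureMeta, ...]
    generators: tuple[ContinuousGen | CategoricalGen, ...]
    label_column: str
    label_set: tuple[str, ...]
    prevalence: tuple[float, ...]
    label_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.feature_meta) != len(self.generators):
            raise ValueError("one generator per feature required")
        if len(self.prevalence) != len(self.label_set):
            raise ValueError("prevalence must cover the label set")
        if abs(sum(self.prevalence) - 1.0) > 1e-9:
            raise ValueError("prevalence must sum to 1")

    @property
    def n_features(self) -> int:
        return len(self.feature_meta)

    def encode_labels(self, raw: Sequence) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.label_set)}
        out = []
        for v in raw:
            s = str(v).strip()
            s = self.label_map.get(s, s)
            if s not in index:
                raise ValueError(f"label {v!r} not in label set {self.label_set}")
            out.append(index[s])
        return np.asarray(out, dtype=int)

    # -- plain-text round trip ---------------------------------------
    def to_dict(self) -> dict:
        feats = []
        for m, g in zip(self.feature_meta, self.generators):
            entry: dict = {"name": m.name, "kind": m.kind, "unit": m.unit}
            if isinstance(g, ContinuousGen):
                entry.update(mean=float(g.mean), sd=float(g.sd),
                             class_shift=[float(v) for v in g.class_shift])
            else:
                entry.update(categories=list(g.categories),
                             base_probs=[float(v) for v in g.base_probs],
                             class_logit_shift=[[float(v) for v in r]
                                                for r in g.class_logit_shift])
            feats.append(entry)
        return {"dataset_id": self.dataset_id, "features": feats,
                "label_column": self.label_column, "label_set": list(self.label_set),
                "prevalence": list(self.prevalence), "label_map": dict(self.label_map)}

    @classmethod
    def from_dict(cls, d: dict) -> "SchemaSpec":
        meta, gens = [], []
        for f in d["features"]:
            meta.append(FeatureMeta(f["name"], f["kind"], f.get("unit")))
            if f["kind"] == CONTINUOUS:
                gens.append(ContinuousGen(f["mean"], f["sd"], tuple(f["class_shift"])))
            else:
                gens.append(CategoricalGen(tuple(f["categories"]), tuple(f["base_probs"]),
                                           tuple(tuple(r) for r in f["class_logit_shift"])))
        return cls(d["dataset_id"], tuple(meta), tuple(gens), d["label_column"],
                   tuple(d["label_set"]), tuple(d["prevalence"]),
                   dict(d.get("label_map", {})))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SchemaSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _cont(name, unit, mean, sd, shifts) -> tuple[FeatureMeta, ContinuousGen]:
    return FeatureMeta(name, CONTINUOUS, unit), ContinuousGen(mean, sd, tuple(shifts))


def _cat(name, categories, base, shifts) -> tuple[FeatureMeta, CategoricalGen]:
    return (FeatureMeta(name, CATEGORICAL, None),
            CategoricalGen(tuple(categories), tuple(base), tuple(tuple(s) for s in shifts)))


def _heart_schema(five_class: bool) -> SchemaSpec:
    if five_class:
        # severity grades 0-4; shifts scale linearly with grade
        grades = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        label_set = ("0", "1", "2", "3", "4")
        prevalence = (0.54, 0.18, 0.12, 0.12, 0.04)
        label_map = {}
    else:
        grades = np.array([0.0, 1.0])
        label_set = ("no_disease", "heart_disease")
        prevalence = (0.54, 0.46)
        label_map = {str(k): ("no_disease" if k == 0 else "heart_disease")
                     for k in range(5)}

    def sh(s):  # continuous shift pattern per class
        return tuple(s * grades)

    def csh(per_cat):  # categorical log-odds shift per class
        return tuple(tuple(g * np.asarray(per_cat)) for g in grades)

    items = [
        _cont("age", "years", 54, 9, sh(0.4)),
        _cat("sex", ("0", "1"), (0.33, 0.67), csh((-0.4, 0.4))),
        _cat("cp", ("1", "2", "3", "4"), (0.1, 0.2, 0.3, 0.4), csh((-0.5, -0.3, -0.2, 0.7))),
        _cont("trestbps", "mmHg", 120, 14, sh(0.45)),
        _cont("chol", "mg/dL", 115, 14, sh(0.9)),
        _cat("fbs", ("0", "1"), (0.85, 0.15), csh((-0.2, 0.2))),
        _cat("restecg", ("0", "1", "2"), (0.5, 0.02, 0.48), csh((-0.3, 0.0, 0.3))),
        _cont("thalach", "bpm", 150, 22, sh(-0.55)),
        _cat("exang", ("0", "1"), (0.67, 0.33), csh((-0.6, 0.6))),
        _cont("oldpeak", "mm", 1.0, 1.1, sh(0.6)),
        _cat("slope", ("1", "2", "3"), (0.46, 0.46, 0.08), csh((-0.4, 0.3, 0.3))),
        _cat("ca", ("0", "1", "2", "3"), (0.58, 0.21, 0.13, 0.08), csh((-0.5, 0.2, 0.4, 0.5))),
        _cat("thal", ("3", "6", "7"), (0.55, 0.06, 0.39), csh((-0.5, 0.2, 0.5))),
    ]
    meta, gens = zip(*items)
    return SchemaSpec("heart", meta, gens, "num", label_set, prevalence, label_map)


def _liver_schema() -> SchemaSpec:
    # positive class ~70% prevalence (ILPD composition)
    sh = lambda s: (0.0, s)
    csh = lambda a, b: ((0.0,) * 2, (a, b))
    items = [
        _cont("age", "years", 45, 16, sh(0.3)),
        _cat("gender", ("Female", "Male"), (0.25, 0.75), csh(-0.2, 0.2)),
        _cont("tb", "mg/dL", 1.0, 0.5, sh(1.0)),
        _cont("db", "mg/dL", 0.3, 0.2, sh(1.0)),
        _cont("alkphos", "IU/L", 200, 80, sh(0.8)),
        _cont("sgpt", "IU/L", 25, 10, sh(1.2)),   # ALT, normal band 0-45
        _cont("sgot", "IU/L", 20, 8, sh(1.2)),    # AST, normal band 0-35
        _cont("tp", "g/dL", 6.8, 0.8, sh(-0.3)),
        _cont("alb", "g/dL", 3.8, 0.7, sh(-0.8)),
        _cont("ag_ratio", None, 1.0, 0.3, sh(-0.6)),
    ]
    meta, gens = zip(*items)
    return SchemaSpec("liver", meta, gens, "selector",
                      ("no_disease", "liver_disease"), (0.30, 0.70),
                      {"2": "no_disease", "1": "liver_disease"})


def _kidney_schema() -> SchemaSpec:
    sh = lambda s: (0.0, s)
    csh = lambda a, b: ((0.0,) * 2, (a, b))

    def cat2(name, cats, base, a, b):
        return _cat(name, cats, base, ((0.0, 0.0), (a, b)))

    items = [
        _cont("age", "years", 50, 16, sh(0.3)),
        _cont("bp", "mmHg", 76, 10, sh(0.5)),
        _cont("sg", None, 1.020, 0.004, sh(-0.8)),
        _cont("al", None, 0.3, 0.5, sh(1.2)),
        _cont("su", None, 0.2, 0.4, sh(0.8)),
        cat2("rbc", ("normal", "abnormal"), (0.85, 0.15), -0.6, 0.6),
        cat2("pcc", ("notpresent", "present"), (0.9, 0.1), -0.5, 0.5),
        cat2("ba", ("notpresent", "present"), (0.95, 0.05), -0.4, 0.4),
        _cont("bu", "mg/dL", 35, 12, sh(1.0)),
        _cont("sc", "umol/L", 90, 15, sh(1.5)),   # serum creatinine, normal 60-120
        _cont("sod", "mEq/L", 140, 4, sh(-0.6)),
        _cont("pot", "mmol/L", 4.4, 0.5, sh(0.8)),
        _cont("hemo", "g/dL", 13.5, 1.6, sh(-1.0)),
        _cont("pcv", "%", 42, 5, sh(-1.0)),
        _cont("wc", "cells/cmm", 7800, 1800, sh(0.4)),
        _cont("rc", "millions/cmm", 4.9, 0.6, sh(-0.8)),
        cat2("htn", ("no", "yes"), (0.65, 0.35), -0.6, 0.6),
        cat2("dm", ("no", "yes"), (0.7, 0.3), -0.5, 0.5),
        cat2("cad", ("no", "yes"), (0.92, 0.08), -0.3, 0.3),
        cat2("appet", ("good", "poor"), (0.8, 0.2), -0.5, 0.5),
        cat2("pe", ("no", "yes"), (0.82, 0.18), -0.5, 0.5),
        cat2("ane", ("no", "yes"), (0.85, 0.15), -0.6, 0.6),
    ]
    meta, gens = zip(*items)
    return SchemaSpec("kidney", meta, gens, "class",
                      ("notckd", "ckd"), (0.60, 0.40))


def make_schema_preset(name: str, five_class: bool = False,
                       prevalence: tuple[float, ...] | None = None) -> SchemaSpec:
    """Return a named schema preset (``heart``, ``liver`` or ``kidney``).

    ``five_class`` switches the heart preset to severity grades 0-4;
    ``prevalence`` overrides the preset class proportions.
    """
    if name == "heart":
        spec = _heart_schema(five_class)
    elif name == "liver":
        spec = _liver_schema()
    elif name == "kidney":
        spec = _kidney_schema()
    else:
        raise ValueError(f"unknown schema preset {name!r}")
    if prevalence is not None:
        if len(prevalence) != len(spec.label_set):
            raise ValueError("prevalence length must match the label set")
        spec = SchemaSpec(spec.dataset_id, spec.feature_meta, spec.generators,
                          spec.label_column, spec.label_set, tuple(prevalence),
                          dict(spec.label_map))
    return spec


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate(schema: SchemaSpec, n: int, effect_size: float = 1.0,
             missing_rate: float = 0.0, seed: int = 0) -> ClinicalTable:
    """Draw a seeded, reproducible clinical table from a schema.

    Labels follow the schema prevalence; continuous features are Gaussian
    with per-class mean shifts scaled by ``effect_size``; categorical
    features follow per-class probabilities; missing markers are injected
    completely at random at ``missing_rate``.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(seed)
    C = len(schema.label_set)
    labels = rng.choice(C, size=n, p=np.asarray(schema.prevalence))

    cols: dict[str, pd.Series] = {}
    for m, g in zip(schema.feature_meta, schema.generators):
        if isinstance(g, ContinuousGen):
            shift = np.asarray(g.class_shift)[labels] * effect_size * g.sd
            vals = g.mean + shift + rng.normal(0.0, g.sd, size=n)
            cols[m.name] = pd.Series(vals, dtype=float)
        else:
            vals = np.empty(n, dtype=object)
            for k in range(C):
                mask = labels == k
                if mask.any():
                    vals[mask] = rng.choice(list(g.categories), size=int(mask.sum()),
                                            p=g.probs(k, effect_size))
            cols[m.name] = pd.Series(vals, dtype=object)

    if missing_rate > 0:
        mask = rng.random((n, schema.n_features)) < missing_rate
        for j, m in enumerate(schema.feature_meta):
            col = cols[m.name].copy()
            col[mask[:, j]] = np.nan
            cols[m.name] = col

    data = pd.DataFrame(cols)
    return ClinicalTable(data, schema.feature_meta, labels,
                         schema.label_set, schema.dataset_id)
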