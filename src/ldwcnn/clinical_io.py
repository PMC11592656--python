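"""Reading, cleaning, normalising and splitting tabular clinical datasets.

Supports the two dialects the public UCI clinical tables ship in: CSV with a
header row, and the flat ``@attribute``/``@data`` subset of ARFF used by the
chronic-kidney-disease file.  ``'?'`` and empty cells are missing markers in
both.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthdata import SchemaSpec

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class SchemaMismatchError(ValueError):
    """File columns do not match the declared schema."""


class CellParseError(ValueError):
    """A cell could not be parsed as the declared feature kind."""


class ZeroVarianceError(ValueError):
    """A continuous feature is constant on the training split."""


class AllMissingColumnError(ValueError):
    """A column contains no observed values, so no statistic can impute it."""


@dataclass(frozen=True)
class FeatureMeta:
    name: str
    kind: str  # CONTINUOUS | CATEGORICAL
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass
class ClinicalTable:
    """Rows of mixed-type clinical features with per-row class labels.

    ``data`` holds one column per entry of ``feature_meta`` (continuous
    columns are float with NaN for missing; categorical columns are object
    with NaN for missing).  ``labels`` are integer codes into ``label_set``.
    """

    data: pd.DataFrame
    feature_meta: tuple[FeatureMeta, ...]
    labels: np.ndarray
    label_set: tuple[str, ...]
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.feature_meta = tuple(self.feature_meta)
        self.labels = np.asarray(self.labels, dtype=int)
        names = [m.name for m in self.feature_meta]
        if list(self.data.columns) != names:
            raise ValueError("data columns do not match feature_meta order")
        if len(self.labels) != len(self.data):
            raise ValueError("label count does not equal row count")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(self.label_set)):
            raise ValueError("labels outside declared label set")

    # -- conveniences -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.feature_meta]

    def meta(self, name: str) -> FeatureMeta:
        for m in self.feature_meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.label_set))

    def to_matrix(self) -> np.ndarray:
        """Dense float matrix; requires all-continuous, complete features."""
        if any(m.kind != CONTINUOUS for m in self.feature_meta):
            raise ValueError("table still holds categorical features; normalize() first")
        if self.has_missing():
            raise ValueError("table has missing values; impute() first")
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(self.data.copy(), self.feature_meta,
                             self.labels.copy(), self.label_set, self.dataset_id)

    def take(self, idx: Sequence[int]) -> "ClinicalTable":
        idx = np.asarray(idx, dtype=int)
        return ClinicalTable(self.data.iloc[idx].reset_index(drop=True),
                             self.feature_meta, self.labels[idx],
                             self.label_set, self.dataset_id)


@dataclass
class NormalizationParams:
    """Training-split statistics: z-score parameters and one-hot categories."""

    means: dict[str, float]
    sds: dict[str, float]
    categories: dict[str, tuple[str, ...]]  # per categorical feature

    def __post_init__(self) -> None:
        bad = [n for n, s in self.sds.items() if not s > 0]
        if bad:
            raise ZeroVarianceError(f"non-positive sd for feature(s) {bad}")


@dataclass
class SplitBundle:
    train: ClinicalTable
    validation: ClinicalTable
    test: ClinicalTable
    ratios: tuple[float, float, float]
    seed: int


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _is_missing(v) -> bool:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return True
    return isinstance(v, str) and v.strip() in ("?", "")


def _coerce_column(raw: pd.Series, meta: FeatureMeta) -> pd.Series:
    s = raw.astype(object).map(lambda v: np.nan if _is_missing(v) else v)
    if meta.kind == CONTINUOUS:
        out = []
        for i, v in enumerate(s):
            if v is np.nan or (isinstance(v, float) and np.isnan(v)):
                out.append(np.nan)
                continue
            try:
                out.append(float(v))
            except (TypeError, ValueError):
                raise CellParseError(
                    f"row {i}: cannot parse {v!r} as numeric for feature {meta.name!r}")
        return pd.Series(out, dtype=float, name=meta.name)
    return pd.Series([np.nan if (isinstance(v, float) and np.isnan(v)) else str(v).strip()
                      for v in s], dtype=object, name=meta.name)


def _read_arff(path: Path) -> pd.DataFrame:
    from scipy.io import arff

    raw, _ = arff.loadarff(str(path))
    df = pd.DataFrame(raw)
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].map(lambda b: b.decode() if isinstance(b, bytes) else b)
            df[col] = df[col].replace({"?": np.nan})
    return df


def read_table(path: str | Path, schema: "SchemaSpec") -> ClinicalTable:
    """Parse a CSV (header row) or ARFF file against a schema preset.

    ``'?'`` and empty cells become missing markers; the label column is
    separated out and encoded against the schema's label set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    if path.suffix.lower() == ".arff":
        df = _read_arff(path)
    else:
        df = pd.read_csv(path, dtype=object, keep_default_na=False,
                         na_values=["?", ""], skipinitialspace=True)
    if len(df) == 0:
        raise ValueError(f"{path} contains no data rows")

    expected = [m.name for m in schema.feature_meta] + [schema.label_column]
    got = list(df.columns)
    if sorted(got) != sorted(expected):
        missing = set(expected) - set(got)
        extra = set(got) - set(expected)
        raise SchemaMismatchError(
            f"columns do not match schema {schema.dataset_id!r}: "
            f"missing={sorted(missing)} unexpected={sorted(extra)}")

    cols = {m.name: _coerce_column(df[m.name], m) for m in schema.feature_meta}
    data = pd.DataFrame(cols)
    labels = schema.encode_labels(df[schema.label_column])
    return ClinicalTable(data, schema.feature_meta, labels,
                         schema.label_set, schema.dataset_id)


def write_csv(table: ClinicalTable, path: str | Path, label_column: str = "class",
              missing_marker: str = "?") -> None:
    """Write in the same dialect :func:`read_table` consumes."""
    df = table.data.copy()
    df[label_column] = [table.label_set[i] for i in table.labels]
    df.to_csv(path, index=False, na_rep=missing_marker)


def write_arff(table: ClinicalTable, path: str | Path, label_column: str = "class",
               relation: str = "clinical") -> None:
    """Write the flat @attribute/@data ARFF subset."""
    lines = [f"@relation {relation}", ""]
    for m in table.feature_meta:
        if m.kind == CONTINUOUS:
            lines.append(f"@attribute {m.name} numeric")
        else:
            cats = sorted({str(v) for v in table.data[m.name].dropna()}) or ["na"]
            lines.append("@attribute %s {%s}" % (m.name, ",".join(cats)))
    lines.append("@attribute %s {%s}" % (label_column, ",".join(table.label_set)))
    lines.append("")
    lines.append("@data")
    for i in range(table.n_rows):
        row = []
        for m in table.feature_meta:
            v = table.data[m.name].iloc[i]
            if pd.isna(v):
                row.append("?")
            elif m.kind == CONTINUOUS:
                row.append(repr(float(v)))
            else:
                row.append(str(v))
        row.append(table.label_set[table.labels[i]])
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def impute(table: ClinicalTable, strategy: str = "impute") -> ClinicalTable:
    """Fill missing cells (column mean / mode) or drop incomplete rows.

    ``strategy='impute'``: continuous missing slots get the column mean,
    categorical the column mode.  ``strategy='drop_rows'``: rows containing
    any missing slot are removed.  Either way the result has no missing
    values and the operation is idempotent.
    """
    if strategy not in ("impute", "drop_rows"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "drop_rows":
        keep = ~table.data.isna().any(axis=1).to_numpy()
        return table.take(np.flatnonzero(keep))
    data = table.data.copy()
    for m in table.feature_meta:
        col = data[m.name]
        if not col.isna().any():
            continue
        observed = col.dropna()
        if observed.empty:
            raise AllMissingColumnError(f"column {m.name!r} is entirely missing")
        if m.kind == CONTINUOUS:
            fill = float(observed.mean())
        else:
            fill = observed.mode().iloc[0]
        data[m.name] = col.fillna(fill)
    return ClinicalTable(data, table.feature_meta, table.labels.copy(),
                         table.label_set, table.dataset_id)


# ---------------------------------------------------------------------------
# Normalisation (z-score continuous, one-hot categorical)
# ---------------------------------------------------------------------------

def _transform(table: ClinicalTable, params: NormalizationParams) -> ClinicalTable:
    cols: dict[str, pd.Series] = {}
    meta: list[FeatureMeta] = []
    for m in table.feature_meta:
        if m.kind == CONTINUOUS:
            z = (table.data[m.name].astype(float) - params.means[m.name]) / params.sds[m.name]
            cols[m.name] = z
            meta.append(FeatureMeta(m.name, CONTINUOUS, m.unit))
        else:
            for cat in params.categories[m.name]:
                name = f"{m.name}={cat}"
                cols[name] = (table.data[m.name].astype(object) == cat).astype(float)
                meta.append(FeatureMeta(name, CONTINUOUS))
    data = pd.DataFrame(cols)
    return ClinicalTable(data, tuple(meta), table.labels.copy(),
                         table.label_set, table.dataset_id)


def normalize(train: ClinicalTable,
              others: Iterable[ClinicalTable] = (),
              ) -> tuple[NormalizationParams, list[ClinicalTable]]:
    """Fit z-score parameters on the training split only and apply everywhere.

    Categorical features are one-hot encoded with the category list frozen
    from the training split (unseen categories in held-out tables map to the
    all-zero row for that feature).  Returns the parameters followed by the
    transformed tables, training table first.
    """
    if train.has_missing():
        raise ValueError("normalize() requires a complete table; impute() first")
    if train.n_rows < 2:
        raise ValueError("need at least 2 training rows to estimate a standard deviation")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    categories: dict[str, tuple[str, ...]] = {}
    for m in train.feature_meta:
        if m.kind == CONTINUOUS:
            col = train.data[m.name].astype(float)
            mu, sd = float(col.mean()), float(col.std(ddof=0))
            if sd <= 0:
                raise ZeroVarianceError(f"feature {m.name!r} has zero variance on the training split")
            means[m.name], sds[m.name] = mu, sd
        else:
            categories[m.name] = tuple(sorted({str(v) for v in train.data[m.name]}))
    params = NormalizationParams(means, sds, categories)
    transformed = [_transform(train, params)] + [_transform(t, params) for t in others]
    return params, transformed


def denormalize(table: ClinicalTable, params: NormalizationParams) -> ClinicalTable:
    """Invert the z-score on continuous features (one-hot columns untouched)."""
    data = table.data.copy()
    for name, mu in params.means.items():
        if name in data.columns:
            data[name] = data[name].astype(float) * params.sds[name] + mu
    return ClinicalTable(data, table.feature_meta, table.labels.copy(),
                         table.label_set, table.dataset_id)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(table: ClinicalTable,
                     ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0) -> SplitBundle:
    """Row-disjoint stratified train/validation/test split.

    Per-class proportions in each part match the input within +-1 row.  The
    same seed always yields the same assignment.  Classes with fewer than 3
    rows trigger a warning and are assigned best-effort to the training part.
    """
    r = tuple(float(x) for x in ratios)
    if len(r) != 3 or any(x < 0 for x in r):
        raise ValueError("ratios must be three non-negative fractions")
    if abs(sum(r) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(r)}")

    counts = table.class_counts()
    rare = np.flatnonzero((counts > 0) & (counts < 3))
    idx_all = np.arange(table.n_rows)
    rare_mask = np.isin(table.labels, rare)
    if rare.size:
        warnings.warn(f"classes {rare.tolist()} have < 3 rows; assigned to training split")
        logger.warning("stratified_split: rare classes %s routed to train", rare.tolist())

    # per-class largest-remainder allocation: each part receives
    # floor(N_k ratio) rows of class k plus at most one remainder row, so
    # per-class proportions deviate from the target by at most one row
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for k in np.flatnonzero(counts):
        k_idx = idx_all[(table.labels == k) & ~rare_mask]
        if k_idx.size == 0:
            continue
        k_idx = rng.permutation(k_idx)
        target = np.asarray(r) * k_idx.size
        alloc = np.floor(target).astype(int)
        frac_order = np.argsort(-(target - alloc), kind="stable")
        for j in frac_order[: k_idx.size - alloc.sum()]:
            alloc[j] += 1
        stops = np.cumsum(alloc)
        parts[0].extend(k_idx[: stops[0]])
        parts[1].extend(k_idx[stops[0]:stops[1]])
        parts[2].extend(k_idx[stops[1]:stops[2]])
    parts[0].extend(idx_all[rare_mask])
    train_idx, val_idx, test_idx = (np.sort(np.asarray(p, dtype=int)) for p in parts)
    return SplitBundle(table.take(train_idx), table.take(val_idx),
                       table.take(test_idx), r, seed)
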