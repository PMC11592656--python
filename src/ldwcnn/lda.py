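"""Linear discriminant analysis as a supervised feature extractor.

Computes per-class means, within- and between-class scatter matrices, and
solves the generalized eigenproblem S_w^{-1} S_B v = lambda v, retaining the
K leading eigenvectors as the projection.  At most C-1 eigenvalues are
nonzero for C classes (rank(S_B) <= C-1).  A small ridge is added to S_w by
default because tiny clinical tables routinely make it singular (n <= d).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .clinical_io import ClinicalTable


class SingularScatterError(np.linalg.LinAlgError):
    """S_w is singular and no ridge was requested."""


@dataclass
class LDAModel:
    class_means: np.ndarray      # (C, d)
    global_mean: np.ndarray      # (d,)
    within_scatter: np.ndarray   # (d, d)
    between_scatter: np.ndarray  # (d, d)
    eigenvalues: np.ndarray      # descending, length d
    projection: np.ndarray       # (d, K), unit-norm columns, sign-fixed
    ridge: float

    @property
    def n_components(self) -> int:
        return self.projection.shape[1]

    def save(self, path: str | Path) -> None:
        """Plain-text export: one header line (K, d, ridge), then the matrix."""
        K, d = self.projection.shape[1], self.projection.shape[0]
        header = f"{K} {d} {self.ridge!r}"
        np.savetxt(path, self.projection.T, header=header, comments="# ")

    @staticmethod
    def load_projection(path: str | Path) -> tuple[np.ndarray, float]:
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
        K, d, ridge = int(header[0]), int(header[1]), float(header[2])
        proj = np.loadtxt(path).reshape(K, d).T
        return proj, ridge


def _matrix_and_labels(table: ClinicalTable) -> tuple[np.ndarray, np.ndarray]:
    return table.to_matrix(), table.labels


def class_means(table: ClinicalTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mean vectors mu_k (C, d) and the global mean mu (d,)."""
    X, y = _matrix_and_labels(table)
    C = len(table.label_set)
    counts = np.bincount(y, minlength=C)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"empty class(es) {empty.tolist()}: cannot form class means")
    mus = np.vstack([X[y == k].mean(axis=0) for k in range(C)])
    return mus, X.mean(axis=0)


def scatter_matrices(table: ClinicalTable) -> tuple[np.ndarray, np.ndarray]:
    """Within-class scatter S_w and between-class scatter S_B.

    S_w = sum_k sum_{n in C_k} (x_n - mu_k)(x_n - mu_k)^T
    S_B = sum_k N_k (mu_k - mu)(mu_k - mu)^T
    """
    X, y = _matrix_and_labels(table)
    mus, mu = class_means(table)
    C = mus.shape[0]
    centered = X - mus[y]
    Sw = centered.T @ centered
    counts = np.bincount(y, minlength=C).astype(float)
    dm = mus - mu
    Sb = (dm * counts[:, None]).T @ dm
    # enforce exact symmetry against floating accumulation order
    Sw = (Sw + Sw.T) / 2.0
    Sb = (Sb + Sb.T) / 2.0
    return Sw, Sb


def _fix_signs(V: np.ndarray) -> np.ndarray:
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def fit_lda(table: ClinicalTable, K: int, ridge: float | None = None) -> LDAModel:
    """Fit the discriminant projection retaining the K leading eigenvectors.

    Solves (S_w + ridge I)^{-1} S_B v = lambda v via the symmetric-definite
    generalized eigensolver.  ``ridge=None`` applies the default
    1e-6 * trace(S_w)/d; ``ridge=0`` requires a non-singular S_w and raises
    :class:`SingularScatterError` otherwise.  Eigenvector columns are unit
    norm with the largest-magnitude component made positive; eigenvalue ties
    keep the solver's ordering under a descending stable sort.
    """
    X, _ = _matrix_and_labels(table)
    d = X.shape[1]
    C = len(table.label_set)
    if not (1 <= K <= min(d, C - 1)):
        raise ValueError(f"K must lie in [1, min(d, C-1)] = [1, {min(d, C - 1)}]")
    Sw, Sb = scatter_matrices(table)
    if ridge is None:
        ridge = 1e-6 * np.trace(Sw) / d
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    Swr = Sw + ridge * np.eye(d)
    try:
        np.linalg.cholesky(Swr)
    except np.linalg.LinAlgError:
        raise SingularScatterError(
            "within-class scatter is singular; pass ridge > 0 (default ridge "
            "1e-6 * trace(S_w)/d handles this)") from None
    evals, evecs = scipy.linalg.eigh(Sb, Swr)
    order = np.argsort(-evals, kind="stable")
    evals = evals[order]
    evecs = _fix_signs(evecs[:, order])
    mus, mu = class_means(table)
    return LDAModel(mus, mu, Sw, Sb, evals, evecs[:, :K], float(ridge))


def project(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X into the K-dimensional discriminant space."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.projection.shape[0]:
        raise ValueError(
            f"X must have {model.projection.shape[0]} columns, got shape {X.shape}")
    return X @ model.projection


def fisher_ratio(model: LDAModel, w: np.ndarray) -> float:
    """Between/within variance ratio along direction w (ridge-regularised)."""
    w = np.asarray(w, dtype=float)
    d = model.within_scatter.shape[0]
    denom = w @ (model.within_scatter + model.ridge * np.eye(d)) @ w
    return float(w @ model.between_scatter @ w / denom)
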