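"""Standardization and the two PCA decompositions (eigengene / eigenassay).

The eigengene (EG) decomposition treats assays as variables: the expression
matrix ``X`` is column-standardized to ``Z`` and the loadings are the
eigenvectors of the n-by-n assay correlation matrix; scores are the
projections of the standardized gene rows, ``S = Z L`` — pseudo expression
values per gene.

The eigenassay (EA) decomposition treats genes as variables and works on
``X^T`` *without* standardization: loadings are the leading eigenvectors of
the m-by-m gene covariance matrix (genes centered across assays), computed
through the n-column dual problem so the m-by-m matrix is never formed.
EA scores are projections of the *uncentered* assay columns onto those
loadings — pseudo assays.

Eigenvector sign is mathematically arbitrary; :func:`fix_orientation`
imposes a deterministic convention, optionally anchored to an assay
grouping so that Group A sits on the positive side of the component.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import (
    AssayGrouping,
    DegenerateColumnError,
    ExpressionMatrix,
    ShapeError,
    ValidationError,
)

#: Eigenvalues below this fraction of the largest are clamped to zero.
EIGENVALUE_CLAMP = 1e-10


@dataclass(frozen=True)
class StandardizedMatrix:
    """Column-standardized expression matrix Z with provenance.

    Each column of ``z_values`` has sample mean 0 and sample standard
    deviation 1 (denominator m-1).  The original column means and standard
    deviations are retained so the transform is invertible.
    """

    z_values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    gene_ids: tuple[str, ...]
    assay_ids: tuple[str, ...]

    @property
    def m(self) -> int:
        return self.z_values.shape[0]

    @property
    def n(self) -> int:
        return self.z_values.shape[1]


@dataclass(frozen=True)
class Decomposition:
    """Loadings, scores and eigenvalues from one PCA run.

    ``mode`` is ``"EG"`` or ``"EA"``.  Loading columns are orthonormal and
    ordered by nonincreasing eigenvalue.  For EG the loadings are n-by-n
    (one entry per assay) and the scores m-by-n (one row per gene); for EA
    the loadings are m-by-n (one entry per gene) and the scores n-by-n
    (one row per assay).
    """

    mode: str
    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    n_components: int

    def proportion_of_variance(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def standardize(x: ExpressionMatrix) -> StandardizedMatrix:
    """Center and scale each assay column: z_ij = (x_ij - mean_j) / sd_j.

    Uses the sample standard deviation (denominator m-1).  A constant
    column has no scale and raises :class:`DegenerateColumnError`.
    """
    vals = x.values
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise DegenerateColumnError(
            f"assay {x.assay_ids[bad[0]]!r} is constant and cannot be standardized"
        )
    z = (vals - means) / sds
    return StandardizedMatrix(z, means, sds, x.gene_ids, x.assay_ids)


def _clamp_eigenvalues(w: np.ndarray) -> np.ndarray:
    w = np.where(w < 0, 0.0, w)
    if w.size and w.max() > 0:
        w = np.where(w < EIGENVALUE_CLAMP * w.max(), 0.0, w)
    return w


def eigengene_decomposition(z: StandardizedMatrix) -> Decomposition:
    """PCA of the assay correlation matrix (EG mode).

    Loadings are eigenvectors of ``Z'Z/(m-1)`` — the sample correlation
    matrix of the assays — ordered by nonincreasing eigenvalue; scores are
    ``Z @ loadings``.  The eigenvalue sum equals n (trace of a correlation
    matrix).
    """
    if z.n < 2:
        raise ShapeError("eigengene decomposition needs at least 2 assays")
    m = z.m
    corr = z.z_values.T @ z.z_values / (m - 1)
    corr = (corr + corr.T) / 2.0  # guard symmetry for eigh
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w = _clamp_eigenvalues(w[order])
    v = v[:, order]
    scores = z.z_values @ v
    d = Decomposition("EG", v, scores, w, z.n)
    return fix_orientation(d, None)

def eigenassay_decomposition(x: ExpressionMatrix) -> Decomposition:
    """PCA of the gene covariance matrix through the dual problem (EA mode).

    Genes are the variables: each gene row is centered across the n assays
    and the top n eigenvectors of the m-by-m gene covariance are obtained
    from the economy SVD of the centered m-by-n matrix (the n-column dual
    problem — identical result, m-by-m never materialized).  Scores project
    the raw, uncentered assay columns onto the loadings.
    """
    if x.n < 2:
        raise ShapeError("eigenassay decomposition needs at least 2 assays")
    vals = x.values
    centered = vals - vals.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = _clamp_eigenvalues(s**2 / (x.n - 1))
    scores = vals.T @ u
    # when m < n (rare: genes usually dwarf assays) only min(m, n)
    # components exist
    d = Decomposition("EA", u, scores, eigenvalues, u.shape[1])
    return fix_orientation(d, None)


def fix_orientation(d: Decomposition, grouping: AssayGrouping | None = None) -> Decomposition:
    """Resolve the arbitrary sign of each component deterministically.

    With a grouping: the component's per-assay values (EG: loading entries,
    EA: score entries) must average at least as high over Group A as over
    Group B.  Without one: the largest-magnitude loading entry is made
    positive.  Idempotent; loading and score columns flip together.
    """
    loadings = d.loadings.copy()
    scores = d.scores.copy()
    if grouping is not None:
        n_assays = loadings.shape[0] if d.mode == "EG" else scores.shape[0]
        grouping.check_against(n_assays)
    for j in range(d.n_components):
        if grouping is not None:
            assay_vals = loadings[:, j] if d.mode == "EG" else scores[:, j]
            flip = assay_vals[grouping.a0].mean() - assay_vals[grouping.b0].mean() < 0
        else:
            col = loadings[:, j]
            flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return replace(d, loadings=loadings, scores=scores)
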