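"""Per-gene contribution algebra and the three differential test statistics.

A PC score is a linear combination of per-assay (EG) or per-gene (EA)
terms; each term is a *contribution*.  Averaging contributions within two
assay groups and differencing gives the differential contribution per gene:

* ``T_diff``  — group-A mean contribution minus group-B mean contribution.
  In EG mode, for gene i and component j:
  ``(1/n_A) sum_{k in A} l_kj z_ik  -  (1/n_B) sum_{k in B} l_kj z_ik``.
  In EA mode this collapses to ``l_pj (xbar_Ap - xbar_Bp)``.
* ``T_scaled`` — ``T_diff`` divided by its estimated standard deviation,
  built from a per-gene pooled variance with the loadings treated as fixed
  constants.  Only meaningful in EG mode: the EA version cancels the
  loading and is exactly the pooled two-sample t.
* ``T_pooled`` — the classical pooled-variance two-sample Student t per
  gene on raw expression values; loading-free, the conventional baseline.

Genes whose pooled standard deviation is zero cannot be scaled; they are
flagged and carry NaN rather than a silent infinity, and rankings place
them last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    AssayGrouping,
    ExpressionMatrix,
    InsufficientReplicationError,
    ValidationError,
)
from .pca import Decomposition, StandardizedMatrix


@dataclass(frozen=True)
class ContributionSet:
    """Group-mean contributions per gene for one component and grouping."""

    mode: str
    pc_index: int
    per_gene_group_a: np.ndarray
    per_gene_group_b: np.ndarray
    grouping: AssayGrouping
    gene_ids: tuple[str, ...]


@dataclass(frozen=True)
class DifferentialResult:
    """Per-gene values of one test statistic for a chosen PC and grouping.

    ``flagged`` marks genes whose denominator vanished; their ``values``
    entries are NaN.  ``variance_estimates`` and ``pooled_sds`` are kept
    when the statistic uses them (``None`` for the unscaled T_diff).
    """

    mode: str
    pc_index: int
    statistic: str
    values: np.ndarray
    flagged: np.ndarray
    gene_ids: tuple[str, ...]
    grouping: AssayGrouping
    variance_estimates: np.ndarray | None = None
    pooled_sds: np.ndarray | None = None


def _check_component(d: Decomposition, j: int) -> None:
    if not 1 <= j <= d.n_components:
        raise ValidationError(
            f"pc_index {j} out of range 1..{d.n_components}"
        )


def eg_group_contributions(
    z: StandardizedMatrix, d: Decomposition, j: int, g: AssayGrouping
) -> ContributionSet:
    """Group-mean eigengene contributions for component j.

    For each gene i: ``gbar_A = (1/n_A) sum_{k in A} l_kj z_ik`` and
    likewise over B.
    """
    if d.mode != "EG":
        raise ValidationError("eg_group_contributions requires an EG decomposition")
    _check_component(d, j)
    g.check_against(z.n)
    loading = d.loadings[:, j - 1]
    ga = (z.z_values[:, g.a0] * loading[g.a0]).sum(axis=1) / g.n_a
    gb = (z.z_values[:, g.b0] * loading[g.b0]).sum(axis=1) / g.n_b
    return ContributionSet("EG", j, ga, gb, g, z.gene_ids)


def ea_group_contributions(
    x: ExpressionMatrix, d: Decomposition, j: int, g: AssayGrouping
) -> ContributionSet:
    """Group-mean eigenassay contributions for component j.

    For each gene p: ``gbar_A = l_pj * xbar_Ap`` with ``xbar_Ap`` the raw
    Group-A mean of gene p (the EA approach never standardizes).
    """
    if d.mode != "EA":
        raise ValidationError("ea_group_contributions requires an EA decomposition")
    _check_component(d, j)
    g.check_against(x.n)
    loading = d.loadings[:, j - 1]
    ga = loading * x.values[:, g.a0].mean(axis=1)
    gb = loading * x.values[:, g.b0].mean(axis=1)
    return ContributionSet("EA", j, ga, gb, g, x.gene_ids)


def t_diff(c: ContributionSet) -> DifferentialResult:
    """Differential contribution per gene: group-A mean minus group-B mean."""
    values = c.per_gene_group_a - c.per_gene_group_b
    return DifferentialResult(
        mode=c.mode,
        pc_index=c.pc_index,
        statistic="t_diff",
        values=values,
        flagged=np.zeros(values.shape, dtype=bool),
        gene_ids=c.gene_ids,
        grouping=c.grouping,
    )


def pooled_sd(values: np.ndarray, g: AssayGrouping) -> np.ndarray:
    """Per-gene pooled standard deviation across the two groups.

    ``s2_pooled = [(n_A - 1) s2_A + (n_B - 1) s2_B] / (n_A + n_B - 2)``.
    Pass the standardized matrix ``z`` or the raw matrix ``x`` depending on
    which variant (standardized / unstandardized levels) is wanted.  Both
    groups need at least two assays.  A gene constant within both groups
    gets pooled sd 0 (the caller flags it).
    """
    if g.n_a < 2 or g.n_b < 2:
        raise InsufficientReplicationError(
            f"pooled variance needs >= 2 assays per group, got {g.n_a} and {g.n_b}"
        )
    values = np.asarray(values, dtype=float)
    g.check_against(values.shape[1])
    va = values[:, g.a0].var(axis=1, ddof=1)
    vb = values[:, g.b0].var(axis=1, ddof=1)
    s2 = ((g.n_a - 1) * va + (g.n_b - 1) * vb) / (g.n_a + g.n_b - 2)
    return np.sqrt(s2)


def t_scaled_eg(
    z: StandardizedMatrix,
    d: Decomposition,
    j: int,
    g: AssayGrouping,
    unit_variance: bool = False,
) -> DifferentialResult:
    """Scaled eigengene statistic: T_diff over its estimated standard error.

    The denominator is
    ``s_pooled_z,i * sqrt( sum_A l^2 / n_A^2 + sum_B l^2 / n_B^2 )``,
    with the loadings treated as fixed.  ``unit_variance=True`` takes the
    standardized per-gene variance as 1 (reasonable when assay variability
    is similar) and drops the per-gene pooled sd.
    """
    if d.mode != "EG":
        raise ValidationError("t_scaled_eg requires an EG decomposition")
    _check_component(d, j)
    g.check_against(z.n)
    loading = d.loadings[:, j - 1]
    coeff = np.sqrt(
        (loading[g.a0] ** 2).sum() / g.n_a**2 + (loading[g.b0] ** 2).sum() / g.n_b**2
    )
    diff = t_diff(eg_group_contributions(z, d, j, g)).values
    if unit_variance:
        sds = None
        denom = np.full(diff.shape, coeff)
    else:
        sds = pooled_sd(z.z_values, g)
        denom = sds * coeff
    flagged = denom == 0
    values = np.divide(diff, denom, out=np.full(diff.shape, np.nan), where=~flagged)
    return DifferentialResult(
        mode="EG",
        pc_index=j,
        statistic="t_scaled",
        values=values,
        flagged=flagged,
        gene_ids=z.gene_ids,
        grouping=g,
        variance_estimates=denom**2,
        pooled_sds=sds,
    )


def t_pooled(x: ExpressionMatrix, g: AssayGrouping) -> DifferentialResult:
    """Classical pooled-variance two-sample t per gene on raw values."""
    g.check_against(x.n)
    sds = pooled_sd(x.values, g)
    diff = x.values[:, g.a0].mean(axis=1) - x.values[:, g.b0].mean(axis=1)
    denom = sds * np.sqrt(1.0 / g.n_a + 1.0 / g.n_b)
    flagged = denom == 0
    values = np.divide(diff, denom, out=np.full(diff.shape, np.nan), where=~flagged)
    return DifferentialResult(
        mode="EA",
        pc_index=0,
        statistic="t_pooled",
        values=values,
        flagged=flagged,
        gene_ids=x.gene_ids,
        grouping=g,
        variance_estimates=denom**2,
        pooled_sds=sds,
    )
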