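"""Numeric stand-in for the visual PC-selection step.

The method selects the component(s) whose per-assay values (EG loadings or
EA scores, plotted against assay number) separate the two candidate groups.
Here that visual judgement becomes a gap statistic: after orienting the
component so Group A sits higher, ``gap = min(A values) - max(B values)``;
a positive gap means the groups do not overlap on that component.  The
normalized gap divides by the larger within-group range, so 1.0 means the
between-group gap is at least as wide as the within-group spread.

A positive gap is a report, never a significance claim — with few assays
per group, chance orderings that look separated are not rare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import AssayGrouping, ValidationError
from .pca import Decomposition


@dataclass(frozen=True)
class SeparationReport:
    """How well one component separates a candidate grouping."""

    pc_index: int
    assay_values: np.ndarray
    gap: float
    normalized_gap: float
    separated: bool


def separation_report(d: Decomposition, j: int, g: AssayGrouping) -> SeparationReport:
    """Gap statistic of component j for grouping g.

    Extracts the component's per-assay values (EG: loading entries; EA:
    score entries), orients so mean(A) >= mean(B), and measures the
    oriented gap between the lowest Group-A value and the highest Group-B
    value.
    """
    if not 1 <= j <= d.n_components:
        raise ValidationError(f"pc_index {j} out of range 1..{d.n_components}")
    vals = (d.loadings if d.mode == "EG" else d.scores)[:, j - 1].copy()
    g.check_against(vals.shape[0])
    if g.n_a + g.n_b < 2:
        raise ValidationError("grouping must cover at least 2 assays")
    a, b = vals[g.a0], vals[g.b0]
    if a.mean() < b.mean():
        vals = -vals
        a, b = -a, -b
    gap = float(a.min() - b.max())
    within = float(max(a.max() - a.min(), b.max() - b.min()))
    if within == 0.0:
        normalized = math.copysign(math.inf, gap) if gap != 0 else 0.0
    else:
        normalized = gap / within
    return SeparationReport(j, vals, gap, normalized, gap > 0)


def select_pcs(
    d: Decomposition, g: AssayGrouping, min_normalized_gap: float = 1.0
) -> list[int]:
    """Components that separate the grouping, best first.

    Returns the 1-based indices of all components with a positive gap and
    ``normalized_gap >= min_normalized_gap``, ordered by normalized gap
    descending; ties go to the smaller component index.  An empty list is
    a valid outcome.
    """
    if min_normalized_gap < 0:
        raise ValidationError("min_normalized_gap must be >= 0")
    reports = [separation_report(d, j, g) for j in range(1, d.n_components + 1)]
    kept = [r for r in reports if r.separated and r.normalized_gap >= min_normalized_gap]
    kept.sort(key=lambda r: (-r.normalized_gap, r.pc_index))
    return [r.pc_index for r in kept]
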