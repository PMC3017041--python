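"""Core containers: expression matrices, assay groupings, run configuration.

The expression matrix is the usual genes-by-assays table of (log-scale)
expression values: ``m`` gene rows, ``n`` assay columns, ``m >> n`` in
practice.  An assay grouping names two disjoint sets of assay columns
(Group A and Group B) between which differential expression is measured.

All indices exposed on these types — assay indices in a grouping, principal
component indices, ranks — are 1-based, matching the conventional
mathematical notation for this method.  Internal array storage is 0-based
NumPy; the conversion happens at the type boundary and never leaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class ShapeError(ValidationError):
    """Matrix has too few rows or columns for the requested operation."""


class ParseError(ValidationError):
    """A cell of a text matrix could not be parsed as a finite real."""


class DegenerateColumnError(ValidationError):
    """An assay column is constant and cannot be standardized."""


class InsufficientReplicationError(ValidationError):
    """A group has fewer than two assays, so no sample variance exists."""


class EmptyRankingError(ValidationError):
    """Every gene is flagged; there is nothing to rank."""


class NoInflectionError(ValidationError):
    """Ranked values are constant in the search window; no gap exists."""


VALID_MODES = ("EG", "EA")
VALID_STATISTICS = ("t_diff", "t_scaled", "t_pooled")
VALID_RANK_BY = ("absolute", "signed_descending", "signed_ascending")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes-by-assays matrix of real expression values.

    Parameters
    ----------
    values
        ``(m, n)`` float array; every entry must be finite.
    gene_ids
        ``m`` unique row identifiers.
    assay_ids
        ``n`` unique column identifiers.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    assay_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ShapeError(f"expected a 2-D matrix, got ndim={vals.ndim}")
        m, n = vals.shape
        if m < 2 or n < 2:
            raise ShapeError(f"need at least 2 genes and 2 assays, got {m}x{n}")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at gene row {bad[0] + 1}, assay column {bad[1] + 1}"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "assay_ids", tuple(str(a) for a in self.assay_ids))
        if len(self.gene_ids) != m:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.assay_ids) != n:
            raise ValidationError(f"{len(self.assay_ids)} assay ids for {n} columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.assay_ids, "assay")

    @property
    def m(self) -> int:
        """Number of genes (rows)."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of assays (columns)."""
        return self.values.shape[1]

    def transposed(self) -> "ExpressionMatrix":
        """Swap the roles of genes and assays."""
        return ExpressionMatrix(self.values.T.copy(), self.assay_ids, self.gene_ids)


@dataclass(frozen=True)
class AssayGrouping:
    """Two disjoint assay groups A and B, given as 1-based column indices.

    The grouping is ordered: the indices are kept in the order supplied.
    ``2 <= n_a + n_b <= n`` must hold against any matrix the grouping is
    applied to; membership bounds are checked by :meth:`check_against`.
    """

    group_a: tuple[int, ...]
    group_b: tuple[int, ...]

    def __post_init__(self) -> None:
        a = tuple(int(i) for i in self.group_a)
        b = tuple(int(i) for i in self.group_b)
        object.__setattr__(self, "group_a", a)
        object.__setattr__(self, "group_b", b)
        if len(a) < 1 or len(b) < 1:
            raise ValidationError("each group needs at least one assay")
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValidationError("repeated assay index within a group")
        if set(a) & set(b):
            raise ValidationError(
                f"groups must be disjoint; shared assays: {sorted(set(a) & set(b))}"
            )
        if min(a + b) < 1:
            raise ValidationError("assay indices are 1-based and must be >= 1")

    @property
    def n_a(self) -> int:
        return len(self.group_a)

    @property
    def n_b(self) -> int:
        return len(self.group_b)

    @property
    def a0(self) -> np.ndarray:
        """Group-A indices as a 0-based integer array (internal use)."""
        return np.asarray(self.group_a, dtype=int) - 1

    @property
    def b0(self) -> np.ndarray:
        """Group-B indices as a 0-based integer array (internal use)."""
        return np.asarray(self.group_b, dtype=int) - 1

    def check_against(self, n: int) -> None:
        """Validate membership against a matrix with ``n`` assay columns."""
        hi = max(self.group_a + self.group_b)
        if hi > n:
            raise ValidationError(f"grouping references assay {hi} but matrix has {n}")
        if self.n_a + self.n_b > n:
            raise ValidationError("grouping covers more assays than the matrix has")

    def swapped(self) -> "AssayGrouping":
        """The same grouping with the roles of A and B exchanged."""
        return AssayGrouping(self.group_b, self.group_a)


@dataclass(frozen=True)
class RunConfig:
    """One ranking run: which decomposition, component, statistic and order.

    ``unit_variance`` selects the scaled-statistic variant that assumes the
    standardized per-gene variance is 1 (appropriate when assay variability
    is similar), dropping the per-gene pooled standard deviation from the
    denominator.
    """

    mode: str = "EG"
    pc_index: int = 1
    statistic: str = "t_diff"
    rank_by: str = "absolute"
    unit_variance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValidationError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if self.statistic not in VALID_STATISTICS:
            raise ValidationError(
                f"statistic must be one of {VALID_STATISTICS}, got {self.statistic!r}"
            )
        if self.rank_by not in VALID_RANK_BY:
            raise ValidationError(
                f"rank_by must be one of {VALID_RANK_BY}, got {self.rank_by!r}"
            )
        if self.pc_index < 1:
            raise ValidationError("pc_index is 1-based and must be >= 1")
        if self.seed < 0:
            raise ValidationError("seed must be nonnegative")
        if self.mode == "EA" and self.statistic == "t_scaled":
            # Scaling the EA differential contribution cancels the loading and
            # collapses onto the ordinary pooled two-sample t; it is exposed
            # only as t_pooled.
            raise ValidationError(
                "t_scaled is not available in EA mode; it is identical to "
                "t_pooled (use statistic='t_pooled')"
            )
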