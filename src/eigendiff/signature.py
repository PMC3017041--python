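"""Gene ranking and signature-size determination.

A *signature* is the head of the ranked gene list above a cutoff.  Two
cutoff rules are provided:

* **Inflection method** — cut where the ranked-statistic curve drops the
  most between consecutive ranks ("the greatest change in the signature
  plot"), i.e. the largest consecutive gap in the sort key within a search
  window.
* **q-value method** — the conventional comparator: two-sided p-values
  from the pooled t with ``n_A + n_B - 2`` degrees of freedom, converted
  to q-values with a single-lambda Storey estimate of the null proportion
  (lambda = 0.5), then cut at a maximum q (commonly 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .datamodel import (
    AssayGrouping,
    EmptyRankingError,
    NoInflectionError,
    ValidationError,
)
from .stats import DifferentialResult

#: Default upper bound of the inflection search window, keeping the search
#: away from degenerate gaps deep in the tail.
DEFAULT_SEARCH_CAP = 5000

#: Single evaluation point for the Storey null-proportion estimate.
STOREY_LAMBDA = 0.5


@dataclass(frozen=True)
class RankedSignature:
    """A full gene ranking plus an optional signature cutoff.

    ``gene_order`` is a permutation of the gene ids, best rank first;
    ``ranked_values`` the statistic in that order and ``ranked_keys`` the
    sort key actually used (``|value|`` for absolute ranking).  Flagged
    genes occupy the final ``n_flagged`` ranks with NaN keys.  The
    signature is ranks ``1..cutoff``.
    """

    gene_order: tuple[str, ...]
    ranked_values: np.ndarray
    ranked_keys: np.ndarray
    rank_by: str
    cutoff: int = 0
    method: str = "none"
    n_flagged: int = 0
    p_values: np.ndarray | None = None
    q_values: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.gene_order)

    def signature_genes(self) -> tuple[str, ...]:
        return self.gene_order[: self.cutoff]


_KEY_FUNS = {
    "absolute": lambda v: np.abs(v),
    "signed_descending": lambda v: v,
    "signed_ascending": lambda v: -v,
}


def rank_genes(r: DifferentialResult, rank_by: str = "absolute") -> RankedSignature:
    """Stable-sort genes by the chosen key, flagged genes last.

    Ties are broken by input gene order; the cutoff is initialized to 0
    (no signature) with method ``"none"``.
    """
    if rank_by not in _KEY_FUNS:
        raise ValidationError(f"unknown rank_by {rank_by!r}")
    ok = ~r.flagged
    if not ok.any():
        raise EmptyRankingError("every gene is flagged; nothing to rank")
    keys = _KEY_FUNS[rank_by](r.values)
    good = np.flatnonzero(ok)
    order_good = good[np.argsort(-keys[good], kind="stable")]
    order = np.concatenate([order_good, np.flatnonzero(~ok)])
    gene_ids = np.asarray(r.gene_ids, dtype=object)
    return RankedSignature(
        gene_order=tuple(gene_ids[order]),
        ranked_values=r.values[order],
        ranked_keys=keys[order],
        rank_by=rank_by,
        n_flagged=int((~ok).sum()),
    )


def inflection_cutoff(
    s: RankedSignature, search_min: int = 1, search_max: int | None = None
) -> RankedSignature:
    """Cut the ranking at the largest consecutive drop in the sort key.

    The cutoff is the rank r in ``[search_min, search_max]`` maximizing
    ``key_r - key_{r+1}``; ties go to the smallest r.  The window defaults
    to ``[1, min(m - 1, 5000)]`` and is clipped to the unflagged head of
    the list.  Constant keys in the window admit no inflection.
    """
    m = s.m
    usable = m - s.n_flagged
    if search_max is None:
        search_max = min(m - 1, DEFAULT_SEARCH_CAP)
    search_max = min(search_max, usable - 1)
    if not 1 <= search_min < search_max <= m - 1:
        raise ValidationError(
            f"invalid inflection window [{search_min}, {search_max}] for m={m}"
        )
    keys = s.ranked_keys
    gaps = keys[search_min - 1 : search_max] - keys[search_min:search_max + 1]
    if np.nanmax(gaps) <= 0:
        raise NoInflectionError("ranked keys are constant in the search window")
    cutoff = search_min + int(np.argmax(gaps))
    return replace(s, cutoff=cutoff, method="inflection")


def storey_pi0(p: np.ndarray, lam: float = STOREY_LAMBDA) -> float:
    """Single-lambda Storey estimate of the null proportion, clamped to (0, 1]."""
    m = p.size
    pi0 = (p > lam).sum() / (m * (1.0 - lam))
    return float(min(1.0, max(pi0, 1.0 / m)))


def qvalue_cutoff(
    t: DifferentialResult,
    g: AssayGrouping,
    max_q: float = 0.05,
    pi0: float | None = None,
) -> RankedSignature:
    """Signature from q-values of the pooled t-statistic.

    Two-sided p-values use the t reference distribution with
    ``n_A + n_B - 2`` degrees of freedom; q-values follow the step formula
    ``q_(i) = pi0 * m * p_(i) / i`` enforced monotone nondecreasing in p
    and capped at 1.  The signature is every gene with ``q <= max_q``,
    ranked by p ascending.  ``pi0=None`` estimates the null proportion
    from the p-values; passing 1.0 reproduces the Benjamini-Hochberg
    adjustment.
    """
    if t.statistic != "t_pooled":
        raise ValidationError("qvalue_cutoff requires the t_pooled statistic")
    if not 0 < max_q < 1:
        raise ValidationError(f"max_q must be in (0, 1), got {max_q}")
    df = g.n_a + g.n_b - 2
    if df < 1:
        raise ValidationError("need n_A + n_B - 2 >= 1 degrees of freedom")
    ok = ~t.flagged
    if not ok.any():
        raise EmptyRankingError("every gene is flagged; nothing to rank")
    good = np.flatnonzero(ok)
    p_good = 2.0 * sps.t.sf(np.abs(t.values[good]), df)
    if pi0 is None:
        pi0 = storey_pi0(p_good)
    if not 0 < pi0 <= 1:
        raise ValidationError(f"pi0 must be in (0, 1], got {pi0}")
    m_tests = good.size
    order_good = good[np.argsort(p_good, kind="stable")]
    p_sorted = 2.0 * sps.t.sf(np.abs(t.values[order_good]), df)
    ranks = np.arange(1, m_tests + 1)
    q = pi0 * m_tests * p_sorted / ranks
    q = np.minimum.accumulate(q[::-1])[::-1]  # monotone from the largest p down
    q = np.minimum(q, 1.0)
    order = np.concatenate([order_good, np.flatnonzero(~ok)])
    gene_ids = np.asarray(t.gene_ids, dtype=object)
    n_flagged = int((~ok).sum())
    pad = np.full(n_flagged, np.nan)
    return RankedSignature(
        gene_order=tuple(gene_ids[order]),
        ranked_values=t.values[order],
        ranked_keys=np.abs(t.values[order]),
        rank_by="absolute",
        cutoff=int((q <= max_q).sum()),
        method="qvalue",
        n_flagged=n_flagged,
        p_values=np.concatenate([p_sorted, pad]),
        q_values=np.concatenate([q, pad]),
    )
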