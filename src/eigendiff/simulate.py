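"""Synthetic expression data with planted differential genes, and the
Monte-Carlo evaluation harness built on it.

The generator emulates a two-condition microarray experiment: every cell
is an independent normal with baseline mean 5.3 (log-scale intensity); a
block of truly differential genes has its Group-A mean shifted up by
``delta``.  Per-gene noise is either a single constant sigma (so
``sigma/delta`` is the coefficient of variation at ``delta = 1``) or drawn
once per gene from a lognormal with natural-scale mean 0.37 and variance
0.37^2, emulating gene-to-gene variance heterogeneity.

The evaluation harness runs the full ranking pipeline (standardize ->
eigengene PCA -> orient PC1 to the grouping -> per-gene statistics ->
rank by absolute value) on each simulated dataset and measures how many
planted genes the top of each ranking captures, plus the power and false
discovery rate of the two signature-cutoff rules.  Every number is a mean
over independent trials and is fully determined by (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import AssayGrouping, ExpressionMatrix, ValidationError
from .pca import eigengene_decomposition, eigenassay_decomposition, fix_orientation, standardize
from .signature import RankedSignature, inflection_cutoff, qvalue_cutoff, rank_genes
from .stats import ea_group_contributions, eg_group_contributions, t_diff, t_pooled, t_scaled_eg

#: Default constant-sigma grid: sigma^2 spanning 0.04 to 1.0.
DEFAULT_SIGMA_GRID = (0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters for one simulated study condition.

    Defaults are the reference condition: 40,000 genes, 10 assays (5 per
    group), 200 planted differential genes, baseline mean 5.3, shift
    ``delta`` applied to the planted genes' Group-A cells.  In the
    ``lognormal`` regime each gene draws its own sigma from a lognormal
    with natural-scale mean ``lognormal_mean`` and variance
    ``lognormal_variance`` (set ``lognormal_on_log_scale=True`` to read
    those two numbers as the log-scale mu and sigma^2 instead).
    """

    m: int = 40000
    n: int = 10
    n_a: int = 5
    n_b: int = 5
    n_sdg: int = 200
    baseline_mean: float = 5.3
    delta: float = 1.0
    sigma_regime: str = "constant"
    sigma: float = 0.2
    lognormal_mean: float = 0.37
    lognormal_variance: float = 0.37**2
    lognormal_on_log_scale: bool = False
    trials: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a + self.n_b != self.n:
            raise ValidationError("n_a + n_b must equal n")
        if not 0 <= self.n_sdg <= self.m:
            raise ValidationError("n_sdg must be in [0, m]")
        if self.sigma_regime not in ("constant", "lognormal"):
            raise ValidationError(f"unknown sigma_regime {self.sigma_regime!r}")
        if self.sigma <= 0 or self.lognormal_mean <= 0 or self.lognormal_variance <= 0:
            raise ValidationError("scale parameters must be > 0")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0 (0 gives a null run)")
        if self.trials < 1 or self.seed < 0:
            raise ValidationError("trials must be >= 1 and seed >= 0")

    def grouping(self) -> AssayGrouping:
        """Group A = the first n_a assays, Group B = the rest (1-based)."""
        return AssayGrouping(
            tuple(range(1, self.n_a + 1)), tuple(range(self.n_a + 1, self.n + 1))
        )


def _lognormal_params(c: SimulationConfig) -> tuple[float, float]:
    if c.lognormal_on_log_scale:
        return c.lognormal_mean, float(np.sqrt(c.lognormal_variance))
    # Solve for log-scale parameters from the natural-scale mean M and
    # variance V: sigma_log^2 = ln(1 + V/M^2), mu_log = ln M - sigma_log^2/2.
    s2 = float(np.log1p(c.lognormal_variance / c.lognormal_mean**2))
    mu = float(np.log(c.lognormal_mean) - s2 / 2.0)
    return mu, float(np.sqrt(s2))


def generate_dataset(
    c: SimulationConfig, trial_index: int = 0
) -> tuple[ExpressionMatrix, frozenset[str]]:
    """One simulated expression matrix plus the planted-gene truth set.

    Genes ``1..n_sdg`` have mean ``baseline_mean + delta`` in the Group-A
    assays (the first ``n_a`` columns) and ``baseline_mean`` everywhere
    else.  Deterministic given ``(c.seed, trial_index)``; trials use
    independent streams, so adding trials never perturbs earlier ones.
    """
    if trial_index < 0:
        raise ValidationError("trial_index must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([c.seed, trial_index]))
    if c.sigma_regime == "constant":
        sigma = np.full(c.m, c.sigma)
    else:
        mu, sd = _lognormal_params(c)
        sigma = rng.lognormal(mu, sd, size=c.m)
    means = np.full((c.m, c.n), c.baseline_mean)
    means[: c.n_sdg, : c.n_a] += c.delta
    values = rng.normal(means, sigma[:, None])
    width = len(str(c.m))
    gene_ids = tuple(f"g{i + 1:0{width}d}" for i in range(c.m))
    assay_ids = tuple(
        f"A{j + 1}" if j < c.n_a else f"B{j - c.n_a + 1}" for j in range(c.n)
    )
    x = ExpressionMatrix(values, gene_ids, assay_ids)
    return x, frozenset(gene_ids[: c.n_sdg])


def pct_sdg_in_top_k(s: RankedSignature, truth: frozenset[str] | set[str], k: int) -> float:
    """Percent of the planted genes found among the top-k ranks."""
    if not truth:
        raise ValidationError("truth set is empty")
    if k > s.m:
        raise ValidationError(f"k={k} exceeds the number of ranked genes {s.m}")
    hit = len(set(s.gene_order[:k]) & set(truth))
    return 100.0 * hit / len(truth)


def rank_statistics(
    x: ExpressionMatrix,
    g: AssayGrouping,
    unit_variance: bool = False,
    include_ea: bool = False,
) -> dict[str, RankedSignature]:
    """The PC1 ranking pipeline: all statistics ranked by absolute value.

    Standardizes, runs the eigengene decomposition, orients PC1 to the
    grouping, then ranks genes by |T_diff|, |T_scaled| and |T_pooled|.
    With ``include_ea`` the eigenassay-mode T_diff ranking is added under
    the key ``"t_diff_ea"``.
    """
    z = standardize(x)
    d = fix_orientation(eigengene_decomposition(z), g)
    out = {
        "t_diff": rank_genes(t_diff(eg_group_contributions(z, d, 1, g))),
        "t_scaled": rank_genes(t_scaled_eg(z, d, 1, g, unit_variance=unit_variance)),
        "t_pooled": rank_genes(t_pooled(x, g)),
    }
    if include_ea:
        da = fix_orientation(eigenassay_decomposition(x), g)
        out["t_diff_ea"] = rank_genes(t_diff(ea_group_contributions(x, da, 1, g)))
    return out


def _capture_rows(
    c: SimulationConfig, ks: tuple[int, ...], unit_variance: bool, include_ea: bool
) -> list[dict]:
    rows = []
    g = c.grouping()
    for trial in range(c.trials):
        x, truth = generate_dataset(c, trial)
        ranked = rank_statistics(x, g, unit_variance=unit_variance, include_ea=include_ea)
        for stat, sig in ranked.items():
            for k in ks:
                rows.append(
                    {
                        "sigma": c.sigma if c.sigma_regime == "constant" else np.nan,
                        "sigma_regime": c.sigma_regime,
                        "delta": c.delta,
                        "trial": trial,
                        "statistic": stat,
                        "k": k,
                        "pct": pct_sdg_in_top_k(sig, truth, k),
                    }
                )
    return rows


def _average(per_trial: pd.DataFrame, c: SimulationConfig) -> pd.DataFrame:
    keys = ["sigma", "sigma_regime", "delta", "statistic", "k"]
    out = (
        per_trial.groupby(keys, dropna=False, sort=False)["pct"]
        .mean()
        .reset_index()
    )
    out["trials"] = c.trials
    out["seed"] = c.seed
    return out


def run_part1(
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    delta: float = 1.0,
    trials: int = 5,
    seed: int = 0,
    ks: tuple[int, ...] = (200, 300, 400),
    unit_variance: bool = False,
    include_ea: bool = False,
    return_trials: bool = False,
    **config_kwargs,
) -> pd.DataFrame:
    """Constant-sigma capture study: top-k recovery over a sigma grid.

    For each sigma and trial, generates a dataset, runs the PC1 ranking
    pipeline, and records the percent of planted genes in the top k for
    each statistic; results are trial-averaged (``return_trials=True``
    keeps the per-trial rows instead).
    """
    if not sigma_grid:
        raise ValidationError("sigma_grid must be nonempty")
    frames = []
    for sigma in sigma_grid:
        c = SimulationConfig(
            sigma_regime="constant",
            sigma=sigma,
            delta=delta,
            trials=trials,
            seed=seed,
            **config_kwargs,
        )
        per_trial = pd.DataFrame(_capture_rows(c, ks, unit_variance, include_ea))
        frames.append(per_trial if return_trials else _average(per_trial, c))
    return pd.concat(frames, ignore_index=True)


def run_part2(
    delta_values: tuple[float, ...] = (1.0, 3.0),
    trials: int = 5,
    seed: int = 0,
    ks: tuple[int, ...] = (200, 400),
    unit_variance: bool = False,
    include_ea: bool = False,
    return_trials: bool = False,
    **config_kwargs,
) -> pd.DataFrame:
    """Heterogeneous-variance capture study: lognormal per-gene sigma."""
    if not delta_values:
        raise ValidationError("delta_values must be nonempty")
    frames = []
    for delta in delta_values:
        c = SimulationConfig(
            sigma_regime="lognormal", delta=delta, trials=trials, seed=seed, **config_kwargs
        )
        per_trial = pd.DataFrame(_capture_rows(c, ks, unit_variance, include_ea))
        frames.append(per_trial if return_trials else _average(per_trial, c))
    return pd.concat(frames, ignore_index=True)


def evaluate_signature_methods(
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    delta: float = 1.0,
    trials: int = 5,
    seed: int = 0,
    max_q: float = 0.05,
    im_window: tuple[int, int] | None = None,
    return_trials: bool = False,
    **config_kwargs,
) -> pd.DataFrame:
    """Signature sizing: inflection cutoff vs the q-value comparator.

    Per sigma and trial: the inflection cutoff is applied to the
    |T_diff^EG| ranking, the q-value cutoff (``q <= max_q``) to the pooled
    t; reports signature size (ss), planted genes captured
    (sdg_in_signature), statistical power (sp = captured / planted) and
    false discovery rate (fdr = (ss - captured)/ss, 0 for an empty
    signature).
    """
    if not sigma_grid:
        raise ValidationError("sigma_grid must be nonempty")
    rows = []
    for sigma in sigma_grid:
        c = SimulationConfig(
            sigma_regime="constant",
            sigma=sigma,
            delta=delta,
            trials=trials,
            seed=seed,
            **config_kwargs,
        )
        g = c.grouping()
        for trial in range(c.trials):
            x, truth = generate_dataset(c, trial)
            ranked = rank_statistics(x, g)
            cuts = {
                "inflection": inflection_cutoff(
                    ranked["t_diff"], *(im_window if im_window else ())
                ),
                "qvalue": qvalue_cutoff(
                    t_pooled(x, g), g, max_q=max_q
                ),
            }
            for method, sig in cuts.items():
                ss = sig.cutoff
                hit = len(set(sig.signature_genes()) & set(truth))
                rows.append(
                    {
                        "sigma": sigma,
                        "delta": delta,
                        "trial": trial,
                        "method": method,
                        "ss": ss,
                        "sdg_in_signature": hit,
                        "sp": hit / len(truth),
                        "fdr": (ss - hit) / ss if ss > 0 else 0.0,
                    }
                )
    per_trial = pd.DataFrame(rows)
    if return_trials:
        return per_trial
    out = (
        per_trial.groupby(["sigma", "delta", "method"], sort=False)[
            ["ss", "sdg_in_signature", "sp", "fdr"]
        ]
        .mean()
        .reset_index()
    )
    out["trials"] = trials
    out["seed"] = seed
    return out
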