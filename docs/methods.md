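# Methods

## Model and assumptions

The method operates on a genes-by-assays matrix `X` (`m` genes, `n`
assays, `m ≫ n`) of real-valued expression levels, assumed log-scale but
not enforced — values are taken as given, with no normalization,
background correction or imputation.  The working statistical model is
independent normal cells, `x_ij ~ N(μ_j, σ_i²)`: each assay may have its
own mean level, each gene its own variance, constant across assays.  That
model is the ground truth of the simulator and the motivation for the
variance formulas; it is never *enforced* on real inputs.

Two dual PCA views are used.  **Eigengene (EG)**: assays are variables;
`X` is column-standardized (sample sd, denominator `m−1`) and the
loadings are eigenvectors of the assay correlation matrix `Z'Z/(m−1)`,
so the eigenvalues sum to `n`.  **Eigenassay (EA)**: genes are variables;
rows are centered across assays (that is what covariance means) but the
matrix is otherwise *not* standardized, and — deliberately — EA scores
and contributions project the raw, uncentered values.  EA loadings come
from the economy SVD of the centered `m × n` matrix: the n-column dual of
the `m × m` covariance eigenproblem, identical in eigenvalues and
eigenvectors for the nonzero spectrum (a unit test checks this against
the directly formed `m × m` covariance at small `m`).  Row-centering
makes the EA spectrum rank-deficient by one; near-zero eigenvalues
(below `1e-10` of the largest) are clamped to zero and their components
retained.

Eigenvector signs are arbitrary, so a deterministic orientation rule is
applied: anchored to a grouping, each component is flipped so its
per-assay values (EG loadings, EA scores) average at least as high over
Group A as over Group B; unanchored, the largest-magnitude loading entry
is made positive.  Loading and score columns always flip together, and
the rule is idempotent.

## Statistics

With disjoint assay groups A, B (sizes `n_A`, `n_B`):

- `T_diff` — difference of group-mean contributions per gene.  EG:
  `(1/n_A) Σ_{k∈A} ℓ_kj z_ik − (1/n_B) Σ_{k∈B} ℓ_kj z_ik`; EA:
  `ℓ_pj (x̄_Ap − x̄_Bp)` (the two-path identity is asserted to 1e-12).
- `T_scaled` (EG only) — `T_diff` divided by its estimated standard
  deviation, treating the loadings as fixed constants (no propagation of
  loading uncertainty):
  `s_pooled,z,i · √(Σ_A ℓ²/n_A² + Σ_B ℓ²/n_B²)`, where the pooled
  variance is `[(n_A−1)s²_A + (n_B−1)s²_B]/(n_A+n_B−2)` over the
  standardized values.  A `unit_variance` variant replaces the per-gene
  pooled sd by 1, appropriate when assay variability is similar; the
  pooled-sd form is the default.
- `T_pooled` — the classical pooled two-sample t per gene on raw values.
  Scaling the EA `T_diff` cancels the loading and reproduces `T_pooled`
  exactly, which is why no EA scaled statistic exists.

Genes whose pooled sd is zero have no defined scaled statistic; they are
flagged, carry NaN (never a silent infinity), and rank last.  No
reference distribution is claimed for `T_diff`/`T_scaled`; p-values exist
only for `T_pooled` (t distribution, df `n_A + n_B − 2`).

## PC selection

The component-selection step is visual in origin (loading/score vs assay
plots); here it is a number: after orientation, `gap = min(A values) −
max(B values)`, positive iff the groups do not overlap.  The normalized
gap divides by the larger of the two within-group ranges ("pooled
within-group range"; the larger-range convention is the conservative
reading), with ±infinity when both groups are degenerate points.  The
default selection threshold `min_normalized_gap = 1.0` demands a
between-group gap at least as wide as the within-group spread.  This is
a report, not a test: with few assays per group, chance separations are
not rare, so no significance is attached.

## Signature cutoffs

**Inflection method**: cut the ranked-key curve (the sort key, `|value|`
for absolute ranking) at the rank `r` maximizing `key_r − key_{r+1}`,
ties to the smallest `r`, searching `[1, min(m−1, 5000)]` by default —
the cap keeps the search off degenerate tail gaps, and the window is
clipped to the unflagged head of the list.  "Greatest change" is
implemented literally as the largest consecutive drop, with no smoothing.
The cutoff is invariant under adding a constant to all keys, but not
under general monotone transforms (gaps change).

**Q-value method** (the conventional comparator): two-sided `T_pooled`
p-values, converted by the step formula `q_(i) = π̂₀ · m · p_(i) / i`,
made monotone from the largest p down and capped at 1; signature =
`q ≤ 0.05` by default.  `π̂₀` is the single-λ Storey estimate at
λ = 0.5, clamped to `(0, 1]` — the smoother-based refinement of the
published q-value procedure is intentionally not replicated, since the
method serves only as a comparator here; with `π̂₀ = 1` the formula is
exactly Benjamini–Hochberg (cross-checked against statsmodels in the
suite).

## Simulator

`generate_dataset` emulates a two-condition experiment:
`x_ij ~ N(5.3 + δ, σ_i²)` for the planted genes' Group-A cells and
`N(5.3, σ_i²)` elsewhere.  Defaults are the reference study condition:
40,000 genes, 10 assays (5 + 5), 200 planted genes, baseline mean 5.3.
Noise regimes: *constant* (`σ_i = σ`, grid σ ∈ {0.2 … 1.0}, i.e. σ²
from 0.04 to 1.0 — so at δ = 1 σ is also the coefficient of variation)
and *lognormal* (`σ_i` drawn once per gene from a lognormal with
natural-scale mean 0.37 and variance 0.37², i.e. log-scale
`σ²_log = ln(1 + V/M²) = ln 2`, `μ_log = ln M − σ²_log/2`; reading the
two numbers as log-scale parameters instead is exposed as
`lognormal_on_log_scale`).  The natural-scale reading is the default
because "mean and variance of the distribution" most plainly describes
the distribution itself.

Each trial draws from an independent stream keyed by
`SeedSequence([seed, trial_index])`, so results are bit-reproducible and
adding trials never perturbs earlier ones.  Reported metrics (top-k
capture percentage, signature size, power = captured/planted, FDR =
(size − captured)/size with 0/0 ≡ 0) are exact means of per-trial values.

What the simulator does *not* emulate: correlation between genes (every
cell is independent — real expression data share per-assay conditions),
heavy-tailed or intensity-dependent noise, missing values, and any
normalization artifacts.  Passing benchmarks here therefore demonstrate
behavior under the stated independence model, not on real arrays.

## Problem sizes and numerical choices

The evaluation harness runs the full reference size (40,000 × 10, five
trials) for the headline capture point — one trial is a 10-column SVD
plus sorts, well under a second.  The null-calibration check uses a
reduced 4,000-gene matrix over 20 trials (chance capture 5% instead of
0.5%) so Monte-Carlo error is measurable at small cost, and the
structural-identity tests use a few hundred genes where the brute-force
`m × m` oracle is feasible.  Degenerate inputs fail loudly and early:
constant assay columns (standardization), singleton groups (pooled
variance), all-flagged rankings, constant ranked keys (no inflection).
Eigenvalue ties fall back to the deterministic order of the symmetric
solver.

## Known limitations

- The variance expressions behind `T_scaled` are approximations (loadings
  treated as fixed); no loading-uncertainty propagation is attempted.
- The inflection cutoff is undefined on constant rankings, sensitive to
  isolated outliers at the top of the list, and has no error control —
  its FDR behavior is an empirical observation under the simulation
  model, not a guarantee.
- Group *discovery* is out of scope: candidate groupings are supplied by
  the user and merely verified by the gap statistic; an automated
  2-partition search would change the method.
- Only dense in-memory matrices are supported; no sparse or streaming
  path.
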