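# eigendiff

PCA-based ranking of genes that express most *differently* between two
groups of assays, for transcriptomics (bulk microarray-style or any
genes-by-conditions matrix with few conditions and many genes).

## The method

Given an `m × n` expression matrix **X** (genes in rows, assays in
columns, `m ≫ n`) and two disjoint assay groups A and B:

1. **Eigengene (EG) mode** — standardize each assay column,
   `z_ij = (x_ij − x̄_j)/s_j`, and take the eigenvectors of the `n × n`
   assay correlation matrix as loading vectors `ℓ_j`; scores are
   `S = Z L`.  Each gene's score on component *j* decomposes additively
   into per-assay *contributions* `g_ijk = ℓ_kj z_ik`.
2. **Eigenassay (EA) mode** — the dual: genes are the variables, **X**ᵀ is
   *not* standardized, loadings live in gene space (computed through the
   n-column dual problem, never an `m × m` matrix) and the per-gene
   contribution is `ℓ_pj x_pi`.
3. Pick the component(s) whose per-assay values separate A from B (a
   positive gap between the lowest A value and the highest B value after
   orientation).
4. Score each gene by the **differential contribution**

   `T_diff = ḡ_A − ḡ_B`,   with `ḡ_A = (1/n_A) Σ_{k∈A} ℓ_kj z_ik` (EG),

   optionally scaled by its estimated standard error (loadings treated as
   fixed):

   `T_scaled = T_diff / [ s_pooled,z √( Σ_A ℓ²/n_A² + Σ_B ℓ²/n_B² ) ]`,

   and compare with the classical pooled two-sample t per gene,
   `T_pooled = (x̄_A − x̄_B)/(s_pooled √(1/n_A + 1/n_B))`.  Scaling the EA
   differential contribution cancels the loading and *is* `T_pooled`
   exactly, so EA scaling is not exposed as a separate statistic.
5. Rank genes (by absolute value, or signed), and cut the signature
   either at the **inflection** — the largest consecutive drop in the
   ranked-statistic curve — or at a maximum Storey **q-value** from
   `T_pooled` p-values (df `n_A + n_B − 2`).

A built-in simulator plants truly differential genes
(`x_ij ~ N(5.3 + δ, σ_i²)` in the Group-A columns of the planted block,
`N(5.3, σ_i²)` elsewhere; `σ_i` constant or lognormal across genes) and a
harness measures top-k capture, statistical power and FDR over trials.

## Worked example

`python examples/rank_simulated_genes.py` simulates 2,000 genes × 10
assays (5 + 5) with 100 planted genes shifted by δ = 1 at σ = 0.2, runs
the PC1 pipeline and prints:

```
  t_diff    captures 100.0% of planted genes in its top 100
  t_scaled  captures  98.0% of planted genes in its top 100
  t_pooled  captures  98.0% of planted genes in its top 100
```

i.e. the loading-weighted differential contribution ranks every planted
gene ahead of all 1,900 null genes, while the per-gene-variance-based
statistics let a couple of noisy null genes slip in.  The other examples
show PC selection (`pc_selection.py`), the two signature cutoffs
(`signature_cutoffs.py`) and a noise-grid benchmark
(`benchmark_grid.py`).

The same operations are available from a shell:

```sh
eigendiff simulate --m 2000 --n-sdg 100 --sigma 0.2 --seed 42 --out sim.tsv
eigendiff rank --matrix sim.tsv --statistic t_diff \
    --group-a 1,2,3,4,5 --group-b 6,7,8,9,10 --out ranked.tsv
eigendiff cutoff --matrix sim.tsv --statistic t_diff --method inflection \
    --group-a 1,2,3,4,5 --group-b 6,7,8,9,10 --out signature.tsv
```

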