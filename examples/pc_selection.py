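"""Find which principal components separate a candidate assay grouping.

Decomposes a simulated matrix in eigengene mode and prints each
component's separation gap for the two planted condition groups — the
numeric counterpart of eyeballing loading-vs-assay plots.
"""

from eigendiff import (
    SimulationConfig,
    eigengene_decomposition,
    fix_orientation,
    generate_dataset,
    select_pcs,
    separation_report,
    standardize,
)

config = SimulationConfig(m=2000, n_sdg=100, sigma=0.3, delta=1.0, seed=11)
matrix, _ = generate_dataset(config, trial_index=0)
grouping = config.grouping()

decomp = fix_orientation(eigengene_decomposition(standardize(matrix)), grouping)
print("PC  eigenvalue  gap      normalized  separated")
for j in range(1, decomp.n_components + 1):
    r = separation_report(decomp, j, grouping)
    print(f"{j:<3} {decomp.eigenvalues[j - 1]:9.3f}  {r.gap:+.4f}  "
          f"{r.normalized_gap:+9.3f}   {'yes' if r.separated else 'no'}")

chosen = select_pcs(decomp, grouping, min_normalized_gap=1.0)
print(f"\nSelected components (gap at least as wide as within-group spread): {chosen}")
print("A positive gap means no assay of one group overlaps the other on")
print("that component; only such components are worth ranking genes on.")
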