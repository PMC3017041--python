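"""Determine signature size two ways: inflection cutoff vs q-values.

On a simulated dataset with 100 planted genes, cuts the |T_diff| ranking
at the largest consecutive drop (inflection method) and, separately,
thresholds Storey q-values of the pooled t at 0.05, then compares the
resulting signature sizes, power and false discovery rate.
"""

from eigendiff import (
    SimulationConfig,
    generate_dataset,
    inflection_cutoff,
    qvalue_cutoff,
    rank_statistics,
    t_pooled,
)

config = SimulationConfig(m=2000, n_sdg=100, sigma=0.2, delta=1.0, seed=7)
matrix, truth = generate_dataset(config, trial_index=0)
grouping = config.grouping()

im_sig = inflection_cutoff(rank_statistics(matrix, grouping)["t_diff"])
qv_sig = qvalue_cutoff(t_pooled(matrix, grouping), grouping, max_q=0.05)

for label, sig in (("inflection (|T_diff|)", im_sig), ("q-value (T_pooled)", qv_sig)):
    hits = len(set(sig.signature_genes()) & truth)
    fdr = (sig.cutoff - hits) / sig.cutoff if sig.cutoff else 0.0
    print(f"{label:<22} size={sig.cutoff:4d}  planted captured={hits:3d}  "
          f"power={hits / len(truth):.2f}  FDR={fdr:.3f}")

print("\nThe inflection cutoff lands where the ranked-statistic curve drops")
print("sharpest — at low noise that is exactly the planted/background edge.")
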