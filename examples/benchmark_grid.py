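"""Run a reduced capture benchmark over a noise grid.

Sweeps constant sigma over three levels at a reduced problem size
(4,000 genes, 100 planted) and prints the trial-averaged percent of
planted genes each statistic ranks in its top 100.  The full-size study
(40,000 genes, 200 planted) is what scripts/acceptance.py reproduces.
"""

from eigendiff import run_part1

table = run_part1(
    sigma_grid=(0.2, 0.5, 1.0),
    delta=1.0,
    trials=3,
    seed=123,
    ks=(100,),
    m=4000,
    n_sdg=100,
)

print(table.pivot(index="sigma", columns="statistic", values="pct").round(1))
print("\nCapture falls as noise grows; the loading-weighted statistics hold")
print("up best while sigma stays below the planted shift (delta = 1).")
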