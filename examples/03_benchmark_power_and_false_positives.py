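"""A miniature power / false-positive benchmark (one genome length, two SNR
levels, both noise families, 3 replicates).

Prints the power table (fraction of planted segments with both breakpoints
recovered within 8 probes) and the mean false-positive breakpoints per
profile by method and noise family.  The full-scale version of this table is
what scripts/acceptance.py recomputes.
"""

from cghbench import SimulationConfig, run_benchmark

grid = [
    SimulationConfig(N=2000, snr=snr, noise_family=fam)
    for snr in (1.5, 3.0)
    for fam in ("gaussian", "student_t_df8")
]
table = run_benchmark(grid, ["cbs", "sara", "lrs"], n_reps=3, seed=11,
                      cbs_n_perm=200)

print("power by (method, width multiplier, snr, noise):")
print(table.power.to_string(index=False))
print("\nmean false-positive breakpoints per profile:")
print(table.fp_mean.to_string(index=False))
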