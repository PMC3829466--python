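"""Run all four segmenters on the same simulated chromosome.

Each method reports breakpoints (CBS, SaRa) or calls (LRS, fused lasso);
printed next to the planted truth so the localisation error is visible.
CBS permutations are reduced to 300 to keep this instant.
"""

from cghbench import (
    CbsConfig,
    SimulationConfig,
    cbs_segment,
    default_tuning,
    flsa_solve,
    lrs_detect,
    sara_detect,
    simulate_profile,
    threshold_segment,
)

series, truth = simulate_profile(SimulationConfig(N=5000, snr=3.0, seed=7))
print("true breakpoints:", [(s.start, s.end) for s in truth.segments])

cps = cbs_segment(series, CbsConfig(n_perm=300, seed=1))
print("CBS breakpoints: ", list(cps))

print("SaRa breakpoints:", list(sara_detect(series)))

calls = lrs_detect(series)
print("LRS calls:       ", [(c.start, c.end, round(c.magnitude, 2)) for c in calls])

lam1, lam2 = default_tuning(series)
fl = threshold_segment(flsa_solve(series, lam1, lam2))
print(f"fused lasso (lam1={lam1:.3f}, lam2={lam2:.3f}) calls:",
      [(c.start, c.end, round(c.magnitude, 2)) for c in fl])
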