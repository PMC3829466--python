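"""Post-processing and method agreement on a heavy-tailed profile.

Heavy-tailed (t8) noise makes the LRS scan emit spurious tiny calls; the
standard 5-probe / 1.5-MAD prune removes them.  Probe-level concordance
(shared called probes / geometric mean of called probes) between LRS and
SaRa is printed before and after pruning.
"""

from cghbench import (
    SimulationConfig,
    lrs_detect,
    probe_concordance,
    prune_calls,
    sara_detect,
    segments_to_calls,
    simulate_profile,
)

series, truth = simulate_profile(
    SimulationConfig(N=5000, snr=2.0, noise_family="student_t_df8", seed=1)
)

lrs_calls = lrs_detect(series)
sara_calls = segments_to_calls(series, sara_detect(series))
print(f"raw calls: LRS {len(lrs_calls)}, SaRa {len(sara_calls)} "
      f"(truth has {len(truth)} segments)")

lrs_p = prune_calls(lrs_calls, series)
sara_p = prune_calls(sara_calls, series)
print(f"after 5-probe / 1.5-MAD prune: LRS {len(lrs_p)}, SaRa {len(sara_p)}")

before = probe_concordance(lrs_calls, sara_calls)
after = probe_concordance(lrs_p, sara_p)
print(f"LRS-SaRa probe concordance: {before.value:.2f} raw -> {after.value:.2f} pruned")
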