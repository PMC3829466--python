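"""Simulate one array-CGH chromosome and gauge how detectable its CNVs are.

Builds a 5000-probe profile carrying five planted segments (widths 1-5 times
ln N), prints each segment with its detectability index T = sqrt(n)*SNR /
sqrt(2 ln N): T well above 1 means a local scan should find it, T near or
below 1 means it sits at the detection boundary.
"""

from cghbench import SimulationConfig, detectability_index, simulate_profile

config = SimulationConfig(N=5000, snr=1.5, noise_family="gaussian", seed=1)
series, truth = simulate_profile(config, rep_index=0)

print(f"profile: {series.label}, {series.n_probes} probes, "
      f"noise sd {config.sigma}, shift {config.mean_shift:+.3f}")
for seg in truth.segments:
    T = detectability_index(seg.width, config.snr, config.N)
    print(f"  segment [{seg.start:4d}, {seg.end:4d})  width {seg.width:2d}  "
          f"shift {seg.mean_shift:+.2f}  T = {T:.2f}")
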