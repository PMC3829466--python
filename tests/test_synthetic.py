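"""The simulated profiles and the detectability index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cghbench.synthetic_data import (
    build_truth,
    detectability_index,
    mean_function,
    sample_noise,
    segment_widths,
    simulate_profile,
)
from cghbench.types import SimulationConfig


class TestBuildTruth:
    def test_widths_at_n5000(self):
        # round(k * ln 5000), ln 5000 ~= 8.5172
        assert segment_widths(5000, (1, 2, 3, 4, 5)) == [9, 17, 26, 34, 43]

    def test_one_segment_per_multiplier_evenly_spaced(self):
        cfg = SimulationConfig(N=5000, snr=2.0)
        truth = build_truth(cfg)
        assert [s.width for s in truth.segments] == [9, 17, 26, 34, 43]
        gaps = [truth.segments[0].start] + [
            b.start - a.end for a, b in zip(truth.segments, truth.segments[1:])
        ]
        assert max(gaps) - min(gaps) <= 1
        assert all(s.mean_shift == cfg.mean_shift for s in truth.segments)

    def test_single_multiplier_centered(self):
        truth = build_truth(SimulationConfig(N=5000, snr=1.0, width_multipliers=(1,)))
        (seg,) = truth.segments
        assert seg.width == 9
        # equal gaps on both sides up to the rounding remainder
        assert abs(seg.start - (5000 - seg.end)) <= 1

    def test_infeasible_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_truth(SimulationConfig(N=60, snr=1.0))

    @given(
        N=st.integers(200, 20000),
        mults=st.sets(st.integers(1, 5), min_size=1, max_size=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_segments_fit_and_never_overlap(self, N, mults):
        cfg = SimulationConfig(N=N, snr=1.0, width_multipliers=tuple(mults))
        try:
            truth = build_truth(cfg)
        except ValueError:
            return  # infeasible layouts must raise, not mis-place
        assert truth.segments[0].start >= 1
        assert truth.segments[-1].end <= N
        for a, b in zip(truth.segments, truth.segments[1:]):
            assert a.end < b.start

    def test_invariant_to_rep_index(self):
        cfg = SimulationConfig(N=2000, snr=2.0, seed=5)
        t0 = simulate_profile(cfg, 0)[1]
        t7 = simulate_profile(cfg, 7)[1]
        assert t0 == t7


class TestNoise:
    def test_gaussian_mean_clt_bound(self):
        x = sample_noise(100_000, "gaussian", seed=1)
        assert abs(x.mean()) < 4 / math.sqrt(100_000)

    def test_t8_rescaled_to_unit_variance(self):
        # Var(t_8) = 8/6 before rescaling by sqrt(6/8)
        x = sample_noise(100_000, "student_t_df8", seed=2)
        assert abs(x.var() - 1.0) < 0.05

    def test_t8_heavy_tails(self):
        x = sample_noise(100_000, "student_t_df8", seed=3)
        kurt = np.mean((x - x.mean()) ** 4) / x.var() ** 2 - 3.0
        assert kurt > 0.5  # theoretical excess kurtosis of t_8 is 1.5

    def test_gaussian_unit_variance(self):
        x = sample_noise(50_000, "gaussian", seed=4)
        assert abs(x.var() - 1.0) < 0.05

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sample_noise(10, "cauchy", seed=0)


class TestSimulateProfile:
    def test_noiseless_limit_equals_mean_function(self):
        cfg = SimulationConfig(N=1000, snr=3.0, seed=9)
        series, truth = simulate_profile(cfg, 0)
        mu = mean_function(cfg, truth)
        resid = series.values - mu
        # residual is exactly sigma * noise: zero-mean, sd sigma
        assert abs(resid.mean()) < 4 * cfg.sigma / math.sqrt(cfg.N)
        np.testing.assert_allclose(np.std(resid), cfg.sigma, rtol=0.1)

    def test_determinism_and_rep_independence(self):
        cfg = SimulationConfig(N=500, snr=1.0, seed=3)
        a = simulate_profile(cfg, 2)[0]
        b = simulate_profile(cfg, 2)[0]
        c = simulate_profile(cfg, 3)[0]
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_segment_mean_within_standard_error(self):
        cfg = SimulationConfig(N=5000, snr=3.0, seed=11)
        series, truth = simulate_profile(cfg, 0)
        seg = truth.segments[-1]  # width 43
        m = series.values[seg.start : seg.end].mean()
        assert abs(m - 3 * cfg.sigma) < 3 * cfg.sigma / math.sqrt(seg.width)


class TestDetectabilityIndex:
    def test_direct_value(self):
        assert detectability_index(26, 1.5, 5000) == pytest.approx(1.853, abs=0.001)

    def test_algebraic_identity_and_linearity(self):
        N = 777
        n = max(1, round(2 * math.log(N)))
        # at n = 2 ln N the index reduces to snr itself
        assert detectability_index(n, 1.3, N) == pytest.approx(
            1.3 * math.sqrt(n / (2 * math.log(N)))
        )
        assert detectability_index(40, 2.4, N) == pytest.approx(
            2 * detectability_index(40, 1.2, N)
        )

    @given(n=st.integers(1, 500), snr=st.floats(0.1, 5), N=st.integers(10, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_width_and_snr(self, n, snr, N):
        t = detectability_index(n, snr, N)
        assert t >= 0
        assert detectability_index(n + 1, snr, N) > t
        assert detectability_index(n, snr * 1.5, N) > t

    def test_degenerate_chromosome_rejected(self):
        with pytest.raises(ValueError):
            detectability_index(10, 1.0, 1)
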