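"""Circular binary segmentation and the shared mBIC machinery."""

import numpy as np
import pytest

from cghbench.cbs import (
    CbsConfig,
    _segment_seed,
    cbs_segment,
    circular_max_stat,
    mbic_backward_select,
    mbic_score,
    permutation_pvalue,
)
from cghbench.types import ChangePointSet, ProbeSeries

from ._oracles import best_subset_mbic, brute_max_arc
from .conftest import make_profile


class TestCircularMaxStat:
    def test_plateau_example(self):
        i, j, t = circular_max_stat(np.array([0.0, 0, 5, 5, 0, 0]))
        assert (i, j) == (2, 4)
        assert t > 10

    def test_constant_vector_zero_stat(self):
        assert circular_max_stat(np.ones(10))[2] == 0.0

    def test_negation_symmetry(self, rng):
        x = rng.normal(size=40)
        assert circular_max_stat(x) == circular_max_stat(-x)

    @pytest.mark.parametrize("m", [6, 13, 25, 60])
    def test_matches_exhaustive_search(self, m, rng):
        for _ in range(5):
            x = rng.normal(size=m)
            x[m // 3 : m // 2] += rng.choice([0.0, 2.0])
            i, j, t = circular_max_stat(x)
            oi, oj, ot = brute_max_arc(x)
            # an arc and its complement encode the same split: compare the
            # induced breakpoint sets, not raw (i, j)
            assert {i, j} - {0, m} == {oi, oj} - {0, m}
            assert t == pytest.approx(ot, rel=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            circular_max_stat(np.zeros(3))


class TestPermutationPvalue:
    def test_constant_segment_p_one(self):
        assert permutation_pvalue(np.ones(8), 0.0, 100, seed=1) == 1.0

    def test_strong_block_is_significant(self):
        # the arc mean is extreme among rearrangements; with a 6-probe block
        # in 24 the chance a permutation keeps the block contiguous is tiny
        x = np.zeros(24)
        x[9:15] = 10.0
        _, _, t = circular_max_stat(x)
        assert permutation_pvalue(x, t, 500, seed=7) < 0.05

    def test_short_block_ties_bound_significance(self):
        # 3 equal spikes in 9 probes stay mutually contiguous in a
        # permutation often enough that p cannot reach 0.05
        x = np.array([0.0, 0, 0, 10, 10, 10, 0, 0, 0])
        _, _, t = circular_max_stat(x)
        p = permutation_pvalue(x, t, 2000, seed=7)
        assert 0.02 < p < 0.15

    def test_seeded_determinism_and_plus_one_correction(self, rng):
        x = rng.normal(size=30)
        _, _, t = circular_max_stat(x)
        p1 = permutation_pvalue(x, t, 200, seed=3)
        p2 = permutation_pvalue(x, t, 200, seed=3)
        assert p1 == p2
        assert 0 < p1 <= 1  # +1 correction keeps p strictly positive


class TestCbsSegment:
    def test_constant_series_no_breakpoints(self):
        cps = cbs_segment(ProbeSeries(np.zeros(50)), CbsConfig(n_perm=50))
        assert len(cps) == 0

    def test_recovers_wide_segment_at_high_snr(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            series, truth = make_profile(
                N=2000, snr=3.0, seed=101, rep=rep, width_multipliers=(5,)
            )
            cps = cbs_segment(series, CbsConfig(n_perm=200, seed=rep))
            seg = truth.segments[0]
            idx = cps.indices
            if idx.size and (
                np.min(np.abs(idx - seg.start)) <= 8
                and np.min(np.abs(idx - seg.end)) <= 8
            ):
                hits += 1
        assert hits >= int(0.95 * reps)

    def test_pure_noise_few_false_breakpoints(self, rng):
        total = 0
        for rep in range(10):
            x = np.random.default_rng(rep).standard_normal(1000)
            cps = cbs_segment(ProbeSeries(x), CbsConfig(alpha=0.01, n_perm=200, seed=rep))
            total += len(cps)
        assert total / 10 < 1.0

    def test_matches_bruteforce_recursion_on_short_series(self, rng):
        """The production scan (pruned kernels, early stopping) must make
        exactly the decisions of a naive recursion sharing its RNG stream."""
        for trial in range(5):
            x = rng.normal(size=55)
            x[20:30] += 2.5
            series = ProbeSeries(x)
            config = CbsConfig(alpha=0.05, n_perm=100, seed=trial)

            def naive(lo, hi, out):
                m = hi - lo
                if m < 4:
                    return
                i, j, t = brute_max_arc(x[lo:hi])
                if t <= 0:
                    return
                p = permutation_pvalue(
                    x[lo:hi], t, config.n_perm, _segment_seed(config.seed, lo, hi)
                )
                if p > config.alpha:
                    return
                if i > 0:
                    out.append(lo + i)
                if j < m:
                    out.append(lo + j)
                naive(lo, lo + i, out)
                naive(lo + i, lo + j, out)
                naive(lo + j, hi, out)

            expected: list[int] = []
            naive(0, 55, expected)
            got = cbs_segment(series, config)
            assert sorted(expected) == list(got)

    def test_lower_alpha_never_adds_breakpoints(self):
        series, _ = make_profile(N=1000, snr=2.0, seed=17)
        loose = cbs_segment(series, CbsConfig(alpha=0.05, n_perm=200, seed=1))
        strict = cbs_segment(series, CbsConfig(alpha=0.005, n_perm=200, seed=1))
        assert len(strict) <= len(loose)


class TestMbic:
    def test_empty_configuration_scores_zero(self, rng):
        series = ProbeSeries(rng.normal(size=100))
        assert mbic_score(series, ChangePointSet.empty(100)) == 0.0

    def test_random_breakpoint_on_noise_scores_negative(self):
        rng = np.random.default_rng(5)
        neg = 0
        trials = 40
        for _ in range(trials):
            series = ProbeSeries(rng.standard_normal(200))
            bp = int(rng.integers(1, 200))
            s = mbic_score(series, ChangePointSet(np.array([bp]), 200))
            neg += s < 0
        assert neg > 0.8 * trials

    def test_true_jump_location_scores_best(self, rng):
        x = rng.normal(size=120)
        x[60:] += 5.0
        series = ProbeSeries(x)
        scores = {
            bp: mbic_score(series, ChangePointSet(np.array([bp]), 120))
            for bp in range(1, 120)
        }
        assert max(scores, key=scores.get) == 60

    def test_empty_segment_rejected(self, rng):
        series = ProbeSeries(rng.normal(size=20))
        with pytest.raises(ValueError):
            mbic_score(series, ChangePointSet(np.array([0]), 20))


class TestMbicBackwardSelect:
    def test_empty_candidates(self, rng):
        series = ProbeSeries(rng.normal(size=30))
        assert len(mbic_backward_select(series, ChangePointSet.empty(30))) == 0

    def test_spurious_candidates_pruned_true_pair_kept(self, rng):
        x = rng.normal(size=100) * 0.3
        x[40:60] += 3.0
        series = ProbeSeries(x)
        cands = ChangePointSet(np.array([15, 40, 60, 75, 88]), 100)
        kept = mbic_backward_select(series, cands)
        assert list(kept) == [40, 60]

    def test_never_decreases_score(self, rng):
        x = rng.normal(size=150)
        x[30:45] += 2.0
        series = ProbeSeries(x)
        cands = ChangePointSet(rng.choice(np.arange(1, 150), size=8, replace=False), 150)
        out = mbic_backward_select(series, cands)
        assert mbic_score(series, out) >= mbic_score(series, cands)
        assert set(out).issubset(set(cands))

    @pytest.mark.parametrize("n_cand", [4, 7, 10])
    def test_agrees_with_exhaustive_best_subset(self, n_cand, rng):
        x = rng.normal(size=80)
        x[20:32] += 2.5
        x[55:60] -= 3.0
        series = ProbeSeries(x)
        cands = np.sort(rng.choice(np.arange(2, 79), size=n_cand - 4, replace=False))
        cands = np.unique(np.concatenate((cands, [20, 32, 55, 60])))

        def score_fn(sub):
            return mbic_score(series, ChangePointSet(np.asarray(sub, dtype=int), 80))

        best_sub, best_score = best_subset_mbic(score_fn, list(map(int, cands)))
        got = mbic_backward_select(series, ChangePointSet(cands, 80))
        assert mbic_score(series, got) == pytest.approx(best_score, rel=1e-9)
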