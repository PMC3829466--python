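# Methods

`cghbench` compares four change-point approaches to CNV calling on array-CGH
log2-ratio profiles — two global (circular binary segmentation, the fused
lasso) and two local (the SaRa sliding-window screener, the LRS bounded-width
scan) — on a common simulation test bed, scoring detection power,
false-positive breakpoints, and probe-level concordance.

## Data model

A chromosome is an ordered vector of probe log2 ratios

    y_i = mu_i + sigma * e_i,        i = 0..N-1,

where `mu` is piecewise constant and 0 on the diploid baseline, and the
`e_i` are i.i.d. with unit variance — either standard normal or Student t
with 8 df rescaled by sqrt(6/8) so that SNR = mu/sigma means the same thing
in both families. Probe indices are the coordinate system throughout
(0-based, half-open); genomic base pairs only appear at the I/O boundary.

## Simulation design

One segment per width multiplier k in {1..5}, of width round(k ln N),
evenly spaced: K segments get K+1 equal gaps (integer remainder appended to
the last gap). Defaults:

| parameter | default | why |
|---|---|---|
| N | 5000 / 10000 / 20000 | typical probes-per-chromosome on a 244K CGH array |
| SNR | 0.8 – 3 | spans undetectable to easy |
| sigma | 0.25 log2 units | puts the SNR-3 shift (0.75) in the range of a one-copy gain (log2(3/2) ≈ 0.58); only the fused-lasso 0.5 calling threshold is sensitive to the absolute scale |
| noise | gaussian, student_t_df8 | the standard assumption and a realistic heavy tail |
| shifts | all gains | signs are irrelevant to every scale- and sign-equivariant step; a config flag enables alternating signs |

Per-replicate noise streams derive from `SeedSequence(seed, spawn_key=(rep,))`,
so replicates are mutually independent and individually reproducible.

The detectability index `T = sqrt(n) * SNR / sqrt(2 ln N)` summarises how
hard a planted segment is: local-scan theory puts the detection boundary at
T ≈ 1.

What the generator does **not** emulate: GC waves, spatial autocorrelation,
dye bias, outlier probes beyond the t tail, or multi-chromosome structure.
Passing benchmarks here therefore demonstrate behaviour under the i.i.d.
piecewise-constant model only; real arrays add correlated artifacts that
favour robust post-processing even more.

## The segmenters

**CBS.** The maximal circular two-sample t statistic over arcs [i, j) is a
monotone transform of Q = (C_j − C_i)² m / (k(m−k)) (C = centred prefix
sums), so the arc search and permutation comparisons run on the Q scale.
Significance is by plain permutation with the +1-corrected p-value
(1+exceed)/(1+n_perm); a split is accepted iff p ≤ alpha (default 0.01,
n_perm 10000, reducible). Two *exact* accelerations keep plain permutation
affordable: (a) a sequential stop once the exceedance count proves
p > alpha, and (b) a per-arc-width bound — Q(k) ≤ range(C)² m / (k(m−k)) —
that lets a permutation scan skip every width that cannot reach the observed
statistic. Both leave every decision identical to the naive scan with the
same RNG stream (tested against a brute-force recursion). Minimum flank
after a split is 2 probes; ties in the arc search go to the smallest (i, j).

**mBIC.** Score of a breakpoint configuration with m breakpoints and
segment lengths n_i:

    (N/2) ln(RSS_0/RSS_m) − (1/2) Σ ln(n_i/N) − m ln N,

zero for the empty configuration. The constants follow the modified-BIC
construction for change-point models; because competing conventions exist,
tests assert ordering properties, not absolute scores. Backward selection
walks the full elimination path (always removing the breakpoint whose
removal scores best, even when nothing improves) and returns the best
configuration visited: stopping at the first non-improving removal strands
spurious breakpoint *pairs* — removing one member of a pair bridging a short
noise segment worsens the fit, removing both restores it — and demonstrably
inflates false positives. The path variant agrees with exhaustive
best-subset selection on small instances (tested to 10 candidates).

**SaRa.** Local diagnostic D_h(x) = mean(y[x, x+h)) − mean(y[x−h, x)) at
bandwidths ceil(ln N) × {1, 2, 3}. Screening keeps x where the standardised
diagnostic |D| sqrt(h/2)/sigma_hat exceeds 2.576 (the two-sided normal 0.01
quantile) and D is a *signed* local maximum within (x−h, x+h): up-jumps
compete with up-jumps and down with down, because the opposite-signed
boundaries of a segment as narrow as h lie inside each other's windows and
unsigned competition silently drops the weaker one, capping power exactly
where the sliding window should shine. The screen is deliberately
pointwise-liberal — mBIC backward selection performs the real model
selection; a familywise (extreme-value) cutoff starves it of candidates and
makes SaRa strictly dominated by CBS at small widths. Same-sign candidates
closer than the smallest window merge to the larger standardised value.
Calling is a separate step: induced segments with |mean| ≥ 1.5 × MAD.

**LRS.** All intervals of width ≤ L (default 100) are standardised,
X = Σ y_k / (sqrt(width) sigma_hat); intervals with |X| above the
extreme-value threshold sqrt(2 ln(N·L)) (natural log) are selected greedily
by score — emit the best, discard overlaps, repeat; ties leftmost then
shortest. The noise scale is estimated from first differences,
MAD(diff)/(0.6745 sqrt 2), which ignores sparse mean shifts; a (near-)
noiseless piecewise-constant profile degenerates that estimate to zero, in
which case the sd of first differences is used instead. Aberrations wider
than L are out of scope by design (a global method's job); an optional flag
merges adjacent same-sign calls.

**Fused lasso.** Minimises Σ(y−β)² + lam1 Σ|β| + lam2 Σ|Δβ|. The solver is
exact: a direct O(N) total-variation sweep for the fusion part, then
soft-thresholding by lam1/2 (the classical decomposition of the joint
minimiser); correctness is certified in tests by a KKT dual certificate and
a discretised exhaustive search. Default tuning follows the smoothing
recipe: a running-median smooth (window 10) provides targets
s1 = ||smooth||₁, s2 = TV(smooth), matched within 5% by alternating
bisection on (lam2, lam1). The smooth's noise floor (within 2 × its own MAD
scale) is zeroed before computing the targets — the crude estimate is meant
to bound the CNV profile, not the noise; without this the fit tracks noise
and the 0.5-threshold segmentation fragments into spurious calls. This
method is retained for benchmark completeness; its power curve is erratic
by construction (an absolute 0.5 call threshold meets shrunken fits) and it
is the weakest performer, consistent with prior comparisons.

## Scoring

A planted segment counts as detected when reported breakpoints lie within 8
probes (inclusive) of both boundaries. A reported breakpoint farther than 8
probes from every true boundary is a false positive; breakpoint methods are
scored on their breakpoints, region methods on both boundaries of each call
(deduplicated). Power aggregates over replicates and genome lengths per
(method, width multiplier, SNR, noise family); false positives aggregate
over everything per (method, noise family) — per-profile counts first, then
a grand mean. Pruning keeps calls with width ≥ 5 (inclusive) and
|magnitude| ≥ 1.5 × MAD (consistency constant 1.4826, full profile).
Probe-level concordance between two call sets is shared-probes divided by
the geometric mean of each set's probe count, 0 when either is empty.

## Problem sizes

The default test-suite benchmark runs N in {2000, 5000}, SNR {0.8, 1.5, 3},
both noise families, 8 replicates, CBS at 300 permutations;
`scripts/acceptance.py` runs the full grid N in {5000, 10000, 20000},
SNR {0.8, 1.5, 2, 3}, 4 replicates per combination, CBS at 500
permutations. These are the package's desk-scale defaults; replicate counts
are the knob to turn for tighter Monte-Carlo error.

## Numerical conventions and degenerate inputs

* Constant segments: arc statistic 0, permutation p-value 1, no calls.
* Perfect separation (zero residual after a split) maps to a large finite t.
* RSS ratios are clamped at 1e-12 relative before logs.
* All "within"/"at least" thresholds (8 probes, 5 probes, 0.5 cut) are
  inclusive.
* Every stochastic step takes an explicit seed; per-segment permutation
  streams derive from (seed, segment bounds) so results do not depend on
  recursion order.

## Known limitations

* Plain permutation makes CBS O(N² n_perm) in the worst case; the pruned
  kernels keep realistic profiles fast, but adversarial near-null profiles
  at N = 20000 are slow — lower n_perm in exploratory work.
* mBIC constants are one convention among several; absolute scores are not
  comparable across conventions.
* The SaRa screening threshold and pooling rule in the original authors'
  software are unpublished; results for SaRa are sensitive to these choices.
* The fused-lasso tuning path of the original CGH software is likewise
  unpublished; its rows are qualitative.
* Concordance operations support real probe tables, but no normalisation or
  array-artifact correction is provided; inputs are assumed normalised log2
  ratios.
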