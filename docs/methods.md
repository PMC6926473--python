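# Methods

This note documents the statistical model behind `oscbias`, the choices
made where the design was genuinely open, and what the synthetic-observer
validation does and does not establish.

## Signal-detection decomposition

Trials are scored along the left→right axis: the hit rate H is
P(respond R | target R) and the false-alarm rate FA is
P(respond R | target L). Sensitivity and criterion follow the
equal-variance Gaussian model,

    d′ = (z(H) − z(FA)) / denom,      c = −½ (z(H) + z(FA)),

with `denom = 2` by default (a √2 variant is selectable via the `denom`
argument throughout). Positive criterion is a leftward response
tendency. Proportions are clamped to `[1/(2n), 1 − 1/(2n)]` before the
probit transform so perfect rates stay finite; the clamp preserves
monotonicity, so the monotonicity properties of d′ and c in H survive
the correction.

Aggregate time courses pool all subjects' valid trials into one hundred
contiguous half-open 10-ms bins over the 0.2–1.2 s SOA window (bin
centers at the left edge + 5 ms). Bins missing either target condition
are flagged undefined and skipped by all fitters. Sensitivity series
carry a slow non-oscillatory decline and are detrended by removing a
least-squares 2nd-order polynomial before sinusoid fitting; criterion
series are analyzed raw. No smoothing is ever applied to analyzed data.

## Fixed-frequency sinusoid fitting and the max-R² permutation test

The oscillation model `f(t) = A·cos(2πft+φ) + a₀` is linear in
`(A cos φ, −A sin φ, a₀)` at fixed frequency, so each fit is the exact
closed-form least-squares solution (negative amplitudes are normalized
to A ≥ 0, φ += 180°). Scans cover 4–12 Hz in 0.1-Hz steps (81
frequencies; the 2-back analyses use a restricted 9.1–9.6 Hz window
because the expected effect there is weak and near the frequency already
identified, shrinking the correction family).

Because 81 correlated fits are evaluated, family-wise error is
controlled by a max-statistic permutation test: each surrogate
randomizes the trial outcomes over the observed SOAs (stimulus and
response travel together, so target-condition counts per bin vary as
they would under the null), is re-binned and re-scanned, and contributes
its *maximal* R² across the grid. The corrected p at frequency f is the
fraction of null maxima at or above the observed R²(f). P-values use the
add-one convention `(1+k)/(1+n_perm)` by default so a permutation p is
never exactly zero; the raw-proportion convention is available
(`add_one=False`) since published permutation p-values are often
reported that way. Surrogate series that lose a bin (possible only in
very small datasets) fall back to an exact per-frequency fit on the
surviving bins.

Amplitude/phase uncertainty at a fixed frequency comes from a
trial-level bootstrap (resampling trials with replacement before
binning). Each draw yields a vector `(A cos φ, A sin φ)`; the amplitude
SEM is the bootstrap standard deviation, the phase SEM the circular
standard deviation of sample phases. Significance of the vector is the
semi-plane sign test: the proportion of bootstrap vectors with negative
projection on the observed mean direction, reported one-tailed and
(doubled, default) two-tailed.

Competing peaks within one series are compared with
`AIC = 2k + n·ln RSS` (k = 2, n = number of bins) and summarized as the
relative likelihood `exp(ΔAIC/2)` of the better peak.

## Single-trial harmonic regression and 2D group statistics

Per subject, the ±1 outcome (accuracy: correct/incorrect; response bias:
right/left) is regressed without any link transformation on
`{1, sin(2πft), cos(2πft)}` plus a ±1 stimulus regressor that absorbs
stimulus imbalance when SOA sampling is non-uniform. The stimulus
regressor is always used for real data and optional for simulated data
with uniform sampling; if all targets fell in one ear it is collinear
with the intercept and dropped with a flag. The (β₁, β₂) pair maps to
amplitude `√(β₁²+β₂²)` and phase `atan2(−β₁, β₂)`, which makes the GLM
phase identical to the cosine-convention phase of the aggregate fit (a
cross-module test holds them to 1e−6 on shared input). For binary ±1
outcomes the fitted amplitude estimates twice the modulation amplitude
of the underlying response *rate*, verified by Monte-Carlo.

Group inference treats each subject's (β₁, β₂) as a point in the plane:

- **Max-vector permutation test.** Surrogates shuffle SOAs within each
  subject, refit all frequencies, vector-average across subjects, and
  contribute the maximal group amplitude over the grid. Shuffling a
  subject's SOAs is equivalent to permuting (outcome, stimulus) pairs
  over fixed SOAs, so the harmonic design matrix is constant per
  frequency and the per-surrogate solutions reduce to batched linear
  algebra (with the stimulus regressor, the only permutation-dependent
  normal-equation blocks are the harmonic×stimulus cross products; the
  stimulus–outcome inner product is permutation-invariant because the
  pair is permuted jointly). A unit test pins the batched solver to a
  plain per-permutation GLM refit.
- **2D t-test.** The scatter is the RMS 2D deviation from the mean
  vector, `SD = √(Σ|v−mv|²/N)`. Deviations are projected on the mean
  direction; the amplitude SEM is the RMS parallel projection divided by
  √(N−1) (a literal N−1 divisor is selectable but dimensionally odd and
  far more conservative), t = |mv|/SEM with df = N−1, two-tailed p. The
  phase SEM uses the perpendicular projection via error propagation.
  *Caveat:* folding the 2D scatter onto the mean direction biases the
  mean amplitude away from zero, so under a true null this test rejects
  at roughly 2–3× the nominal rate (measured ≈13% at α = 0.05 with
  N = 14). It is reported for comparability; calibrated family-wise
  inference in this package comes from the permutation tests, whose
  type-I error is verified by simulation.
- **Bayes factor.** The BIC approximation
  `BF₁₀ ≈ (1 + t²/df₂)^{n/2}/√n`, reported as log₁₀. Base and the df
  convention are arguments; published values computed from this family
  of approximations vary with toolbox conventions, so log-BFs should be
  compared qualitatively.

## Circular statistics

Across-subject phase coherence uses the Rayleigh test on unit-normalized
phases (amplitude weighting is available but off by default, matching
the use of unit mean vectors in phase plots): z = nR̄² with the standard
small-sample p approximation. Mean-direction differences between
conditions use the Watson–Williams F test with the usual concentration
correction `K = 1 + 3/(8κ̂)`; a validity warning fires when the pooled
resultant is below 0.45. Angles are degrees at the API surface, radians
internally; differences are reported on (−180°, 180°].

## Serial dependence

For lag k = 1…5, each subject's trials are split by the k-back stimulus
(or response) ear and the criterion is computed within each split,
pooled over SOA. The group statistic is a paired two-tailed t-test on
the per-subject (c | back = L) − (c | back = R) differences; a positive
difference is assimilative. Bonferroni correction multiplies raw p by
the number of lags *without capping* (so corrected values above 1 are
possible and signal clear non-significance); a capped variant and BH-FDR
are provided. Mirroring every ear label negates the criterion within
each split and simultaneously swaps the split labels, so the contingent
difference is invariant under a full L↔R relabeling while the per-split
criteria negate and swap — the symmetry the tests assert.

History labels are defined on the as-presented trial sequence, including
trials later excluded by filtering, because the subject experienced
those trials; labeling on the retained sequence is selectable
(`on="retained"`). Pattern codes concatenate lowercase history ears
(oldest first) with the uppercase current stimulus ear (`lrL` = L two
back, R one back, L now). Congruency schemes: 1-back (lL∪rR vs lR∪rL),
2-back given 1-back incongruent (lrL∪rlR vs rrL∪llR), and totally
congruent/incongruent (llL∪rrR vs rrL∪llR). Note that a naive reading of
"2-back incongruent" as rrL∪llL would mix a congruent pattern into the
incongruent set; the implementation uses rrL∪llR, consistent with the
totally-incongruent definition.

## Exclusion filtering

Trials are flagged invalid (never dropped or reordered) if (a) the
response precedes target onset (rt ≤ 0) or lands after the 2.0-s noise
offset (soa + rt > 2.0 s; the noise duration is configurable), (b) the
reaction time falls outside the subject's central 99% percentile
interval, or (c) the intensity falls outside the subject's central 95%
percentile interval. Percentile (distribution-free) intervals implement
the "confidence interval" rules because they are robust and standard in
psychophysics. Rules apply in that order; a subject left with fewer than
20 valid trials triggers a warning but is retained.

## The synthetic observer

The generator emulates the statistical structure the analysis assumes,
with the design constants of the emulated experiment: 14 subjects ×
2,800 trials, equiprobable ears, SOA uniform on 0.2–1.2 s, ITI
1.2–2.2 s (nuisance), ~75% accuracy by staircase.

Evidence on each trial is `X ~ N(s·(δ/2)·λ_e(t), 1)` with s = ±1 for
the stimulated ear and t = SOA. The stimulated ear's gain is

    λ_e(t) = 1 + a·cos(2πft + φ_e),   φ_L = φ_R + 180°,

active only if ear e received a target within the previous `gate_depth`
(default 2) trials — the gate is binary by default; a per-trial
exponential decay factor is exposed (`gate_decay`) because the
persistence law of such history gating is not constrained by available
evidence. The oscillation is phase-locked to noise onset. The response
is "R" iff X exceeds the decision threshold
`c₀ − bias_2back·s₂ + alt_1back·r₁` (s₂ = signed 2-back stimulus,
r₁ = signed 1-back response), injecting an assimilative 2-back stimulus
bias (default 0.1) and a weak repulsive response-alternation bias
(default 0.05). Closed-form consequences used as oracles: on mutually
gated antiphase trials the measured criterion is
`−(δ/4)(λ_R − λ_L) = (δa/2)·cos(2πft + φ_R + 180°)` while d′ is exactly
constant — the criterion-only dissociation — and with the oscillation
off, P(correct) = Φ(δ/2) so δ = 2Φ⁻¹(0.75) ≈ 1.349 gives 75% accuracy.

Intensity is controlled by one accelerated stochastic-approximation
(Kesten) staircase per ear: `level −= step/(1+shifts)·(outcome − 0.75)`,
with `shifts` counting outcome reversals. The staircase converges to
`θ + σ·Φ⁻¹(0.75)` for a subject with psychometric function
Φ((level−θ)/σ) (verified to < 1 dB); generative sensitivity maps from
intensity as `δ = 2(level−θ)/σ` with σ = 4 dB and subject thresholds
drawn from N(55, 3) dB. Reaction times are pure nuisance (lognormal,
median 0.6 s, σ = 0.35) present only to exercise the exclusion filters;
the osc_amp default of 0.4 produces a criterion modulation an order of
magnitude clearer than typical empirical effects, which is intentional:
the generator is a validation instrument with unambiguous ground truth,
not a calibrated model of any particular dataset.

**What passing tests show — and don't.** The simulations demonstrate
that the pipeline recovers the generative frequency, phase and gating
structure, that the max-statistic tests control family-wise error at
nominal level under the null generator, and that injected serial biases
are recovered to stated tolerance. They do not establish anything about
real listeners: the generator has no drift in thresholds beyond the
staircase, no lapses, no RT–accuracy coupling, no block structure in
performance, and its oscillation is a pure stationary sinusoid. Results
on real data therefore rely on the permutation machinery, not on the
generator resembling the data.

## Numerical choices and problem sizes

- Permutation/bootstrap defaults are 2,000 draws; analysis entry points
  accept any count, and the bundled acceptance script uses 600 draws per
  test (criterion signals in the default generator sit far from the 5%
  tail, and 600 draws resolve corrected p to ~0.002). The test suite's
  type-I calibration uses 100 independent null experiments of 6 subjects
  × 600 trials at 200 permutations each — the family-wise error property
  being checked does not depend on problem size.
- Frequency ties in a scan resolve to the lower frequency; undefined
  bins are dropped rather than imputed; weighted fitting by bin count is
  available but off by default.
- All stochastic steps take explicit integer seeds; the pipeline derives
  per-stage sub-seeds from the run seed by hashing, records them in the
  manifest, and reruns of an identical config are bit-identical.
- Degenerate inputs: zero-amplitude vectors make the semi-plane test and
  mean direction undefined (errors, not NaNs); zero dispersion across
  subjects flags the t-test degenerate with t = ∞; all-one-ear subjects
  drop the stimulus regressor with a flag.

## Known limitations

- The 2D t-test's nominal null is optimistic (see above); use the
  permutation tests for calibrated inference.
- The Watson–Williams test assumes comparable, reasonably high
  concentrations; the implementation warns rather than refuses outside
  its comfort zone.
- The harmonic GLM treats ±1 outcomes linearly (by design, matching the
  aggregate pipeline); logistic links are deliberately out of scope.
- Aggregate binning assumes pooled stationarity across subjects; the
  per-subject GLM route exists precisely to check that no single subject
  drives an aggregate effect.
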