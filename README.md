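# oscbias

Analysis toolkit for **behavioral oscillations and serial dependence in
dichotic 2AFC tone detection**, with a matched synthetic observer for
end-to-end validation.

## The problem

In a dichotic detection experiment, a listener hears 2 s of independent
white noise in each ear; a brief near-threshold tone is played to one ear
at a random stimulus-onset asynchrony (SOA, 0.2–1.2 s after noise onset)
and the listener reports the ear of origin. Performance is decomposed with
signal detection theory along the left→right axis,

    d′ = (z(H_right) − z(FA_left)) / 2
    c  = −½ · (z(H_right) + z(FA_left))        (c > 0 ⇒ leftward bias),

where the hit rate is P(respond R | target R) and the false-alarm rate is
P(respond R | target L). The scientific questions the package addresses:

1. Does the decision criterion *c* (and/or sensitivity d′) oscillate as a
   function of SOA in the alpha band, time-locked to noise onset?
2. Are such oscillations gated by stimulus history — present only when a
   recent previous target occupied the same ear (congruent trials)?
3. What are the average (non-oscillatory) serial-dependence effects of the
   preceding 1–5 stimuli and responses?

It is aimed at psychophysicists analyzing trial tables of this design,
and at methodologists who want a tested reference implementation of the
statistical machinery: fixed-frequency sinusoid fitting with max-statistic
permutation correction, single-trial harmonic regression with 2D vector
group statistics, circular phase tests, and history-contingent criterion
analyses.

## Methods at a glance

- **Aggregate time courses** — trials pooled over subjects, grouped into
  one hundred 10-ms SOA bins; per bin a (d′, c) point; sinusoid
  `A·cos(2πft+φ)+a₀` fitted at each frequency of a 4–12 Hz grid (0.1-Hz
  steps) by exact linear least squares. Family-wise significance from a
  **max-R² permutation test** (surrogates randomize responses over SOAs;
  the null is the distribution of the maximal R² over the whole grid).
  Amplitude/phase variability from a trial-level bootstrap with a
  semi-plane sign test. Competing spectral peaks compared with
  `AIC = 2k + n·ln RSS`.
- **Individual-subject harmonics** — per subject, ±1 outcomes regressed on
  `{1, sin(2πft), cos(2πft), stimulus}` without binning; the (β₁, β₂) pair
  is an amplitude/phase vector. Group inference by vector averaging, a
  **max-vector permutation test**, a one-sample 2D t-test, and a
  BIC-style Bayes-factor approximation `BF₁₀ ≈ (1+t²/df)^{n/2}/√n`.
- **Circular statistics** — Rayleigh test of phase coherence across
  subjects and the Watson–Williams test for per-ear phase differences.
- **Serial dependence** — per-subject criterion split by the n-back
  stimulus or response ear (lags 1–5), paired t-tests with uncapped
  Bonferroni (or BH-FDR) correction.
- **Synthetic observer** — a seeded generative model of the experiment:
  staircase-controlled sensitivity, and an ear-specific multiplicative
  gain `λ_e(t) = 1 + a·cos(2πft+φ_e)` that is switched on only for the
  `gate_depth` trials following a target in that ear, with antiphase ears.
  Antiphase gains cancel in d′ and sum in criterion, so the generator
  reproduces the criterion-only, congruency-gated oscillation the analysis
  is designed to detect — with known ground truth.

## Worked example

```python
import oscbias as ob

cfg = ob.ObserverConfig(seed=1)                      # 14 subjects x 2800 trials
data = ob.label_history(ob.filter_trials(ob.simulate_dataset(cfg)), depth=2)

cong = ob.congruency_split(data, "1back")["congruent"]
scan = ob.scan_frequencies(ob.bin_by_soa(cong, measure="criterion"),
                           ob.frequency_grid())
null = ob.permutation_max_r2(cong, "criterion", n_perm=600, seed=2)
print(f"peak {scan.best.freq:.1f} Hz, R2 = {scan.best.r2:.2f}, "
      f"amp = {scan.best.amp:.3f}, phase = {scan.best.phase_deg:.0f} deg, "
      f"corrected p = {null.p_at(scan.best.freq):.4f}")

print(ob.serial_table(data, max_back=2)[
    ["nback", "mean_diff", "t_stat", "p_corrected", "log_bf"]].round(4))
```

Output:

```
peak 9.4 Hz, R2 = 0.84, amp = 0.295, phase = 177 deg, corrected p = 0.0017
 nback  mean_diff  t_stat  p_corrected  log_bf
     1    -0.0543 -3.4230       0.0091  1.3803
     2     0.1846 12.8995       0.0000  7.4061
```

The congruent-trial criterion oscillates at the generative 9.4 Hz with
phase ≈ 180° at noise onset and survives family-wise correction. The
serial table shows the injected structure: an assimilative 2-back
stimulus effect (positive difference: criterion follows the 2-back ear)
and a weaker *negative* 1-back effect produced by response alternation
masking the stimulus-driven assimilation.

A command-line interface wraps the same pipeline
(`oscbias simulate|filter|serial|split|scan-aggregate|scan-glm|circular|run-all`);
`run-all` executes every stage from a YAML config and writes CSV tables
plus a JSON manifest recording every seed.

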