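# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `sfgsim`. Default values are stated with their
rationale; all of them are configurable through the dataclasses they live
in.

## Stimulus model (`sfgsim.stimulus`, `sfgsim.iso226`)

A stimulus is 40 chords × 50 ms (2000 ms) of concurrent pure tones on a
frequency grid of 129 log-equally spaced values spanning 179–7246 Hz.
The grid's adjacent-step ratio is (7246/179)^(1/128) ≈ 1.0293, i.e. close
to half a semitone. The published description of this stimulus family is
internally inconsistent ("129 values equally spaced with one semitone step"
over 179–7246 Hz cannot all hold: 128 semitone steps would span ~10.7
octaves, the interval spans ~5.3); we resolve it as 129 log-equally spaced
values over the stated interval, which matches the antecedent stimulus
literature, and express figure motion in grid steps. A rising figure
advances `figure_step = 2` grid indices (≈ one semitone) per chord
transition for 10 chords.

Conventions chosen where the design was open:

* **Figure onset** is drawn uniformly from chord positions 7–31 (1-based),
  so a 10-chord figure always fits into 40 chords. (The stated upper
  position of 33 would let the figure overrun the stimulus.)
* **Tone-count conservation:** every chord of a stimulus carries
  `coherence + n_background` tones — figure chords as coherence figure
  tones plus background, all other chords as i.i.d. background — so figure
  and no-figure stimuli are indistinguishable by tone count.
* **Background sampling** is uniform with replacement (duplicate
  frequencies within a chord allowed); figure start indices are sampled
  without replacement from the starts whose full trajectory stays on-grid.
* **Audio rendering:** each tone is a sine scaled by its ISO 226:2003
  equal-loudness gain at the 60-phon contour (a comfortable listening
  level), shaped by 10 ms raised-cosine (cos²) on/off ramps inside its
  chord slot; chords abut with no gap and no cross-chord smoothing. The
  summed waveform is RMS-normalized to a target of 0.05 full scale (so LN
  and HN stimuli have equal RMS) and must not clip afterwards; 16-bit PCM
  at 44.1 kHz on export. The ISO 226 gains are computed from the
  standard's 29 tabulated (α_f, L_U, T_f) parameters interpolated on
  log-frequency; the implementation reproduces the standard's reference
  point (99.85 dB SPL at 20 Hz on the 40-phon contour) and is exactly 1 at
  1 kHz by construction.

## Observer model (`sfgsim.cohort`)

The parametric observer answers yes on a figure trial with probability

    p(yes) = γ + (1 − γ − δ) · (1 − exp(−(k·SNR/SNR_T)^β)),

a Weibull in the stimulus SNR (figure:background tone ratio), where k pins
p = target_p at the threshold SNR_T. Defaults: slope β = 3.5, guess rate
γ = 0.2, lapse δ = 0.02, target_p = 0.85 — standard yes/no QUEST settings;
published SFG experiments rarely document their exact staircase
constants. The
threshold is specified as a coherence level under 20-tone chords and
converted to SNR_T internally, which makes one observer consistent across
both staircases: stage 1 moves SNR via coherence at fixed total, stage 2
via added background at fixed coherence. No-figure trials draw from a
constant false-alarm rate (default 0.2, matching γ). RTs are shifted
lognormal (shift 150 ms, median ≈ 150 ms above shift, σ = 0.4) — a shape
convention only, no decision model behind it.

A stimulus-domain observer is also provided: it computes the longest run
of tones advancing exactly `figure_step` indices across consecutive
chords, adds Gaussian internal noise, and answers yes above a criterion.
Note that a single coherent tone already produces a run of the full figure
length, so this statistic separates figure from no-figure stimuli almost
perfectly regardless of coherence; it is a temporal-coherence detector,
not a graded-difficulty model, and the parametric observer is the default
everywhere.

## QUEST staircases (`sfgsim.quest`)

The posterior over candidate thresholds is a discretized Gaussian prior
updated by the Weibull likelihood of each response; placement is at the
posterior mean (mode/quantile available). Stage 1 runs on the coherence
axis (grid 1–19, grain 0.05, prior mean 10, sd 4), recommends integer
coherences clamped to [2, 18] (round-half-up), and keeps 20 tones per
chord. Stage 2 runs on log-SNR (grain 0.01; prior mean 0.3 below the LN
point), converting recommendations to integer added-background counts in
[0, 40]. Both stages present 50% figure / 50% catch trials; the staircase
tracks the hit rate, so only figure trials update the posterior (catch
trials carry no threshold information under this observer model). Both run
80 base trials and extend in blocks of 20 while the posterior SD exceeds
the median spacing of the admissible stimulus levels (1.0 coherence units
in stage 1; the median |Δ log-SNR| over successive added-tone counts in
stage 2), capped at 200 trials. The stage-2 level spacing is finer than
the reachable posterior SD for many observers, so stage 2 frequently runs
to the cap; the returned estimate is the posterior mean either way and the
`converged` flag records which exit was taken.

Because the staircase's assumed psychometric family matches the simulated
observers', the converged stimulus levels sit at the designed operating
points: measured mean hit probability ≈ 85% (stage 1) and ≈ 65% (stage 2),
within ±3 percentage points over 50 observers (the residual deviation is
dominated by integer quantization of the stimulus levels).

## Synthetic cohort

Group sizes default to 20 young / 13 normal-hearing elderly / 16
hearing-impaired elderly. Coherence thresholds are Gaussian per group
(sd 1.2) with means 10.5 / 11.0 / 14.0: the +3 shift of the
hearing-impaired group is the built-in effect the analyses should recover,
consistent with published reports of ~55% vs ~70% of 20 tones needed for
the 85% point in these two groups. Audiograms are flat-mild for young listeners and sloping for
elderly ones; hearing-impaired audiograms are guaranteed ≥ 1 threshold
above 45 dB at 4–8 kHz (the defining criterion), normal-hearing elderly
are capped below it, and inter-ear differences stay under the 20 dB
exclusion rule. Digit spans are generated fields only (no task
simulation). Classification: elderly with any threshold > 45 dB at
250–8000 Hz → hearing-impaired; ≥ 20 dB inter-ear difference → exclusion
flag.

## Synthetic EEG and ERP templates

Channels are restricted to C3/Cz/C4/P3/Pz/P4 at 1 kHz — the leads the
measurements use. The record is per-channel independent pink-noise
(1/f amplitude spectrum, sd 8 µV) plus, for every correct-response figure
trial, two Gaussian bumps time-locked to figure onset:

* **ORN:** −3 µV, FWHM 80 ms, latency 280 ms (young) / 421 ms (elderly),
  weights C3 1.0 > Cz 0.8 ≥ C4 0.7 (left-dominant fronto-central).
* **P400:** +4 µV young, ×0.7 for elderly, FWHM 150 ms, latency 750 ms,
  weights Pz 1.0 > P3 = P4 0.75 (midline parietal).

Latency and topography defaults follow the published group-level ORN/P400
results so that pipeline recovery doubles as an end-to-end check; the
amplitudes and widths are fixture conventions (group amplitudes are
typically reported only graphically). "Width" is Gaussian FWHM. Artifacts are
300 ms Hann bursts of ±150 µV on all channels, Poisson at 2/min. What this
generator does *not* emulate: correlated inter-channel noise (available as
an option but off by default), alpha rhythms, eye/muscle artifacts with
realistic topography, latency jitter across trials, or any dependence of
the ERP on stimulus parameters beyond correctness — so passing recovery
tests demonstrates the *pipeline's* correctness, not realism of the EEG.

## ERP pipeline conventions (`sfgsim.erp`)

* Band-pass 0.5–80 Hz, Kaiser-window FIR (β = 5.65326, 18112 taps at
  1 kHz). An even tap count is bumped by one so the symmetric FIR has
  integer group delay; 'same'-mode convolution is then exactly zero-phase.
* Epochs are half-open sample windows [−800, +2300) ms → 3100 samples at
  1 kHz; baselines use [−800, 0) ms. No-figure trials reuse the figure
  trials' onsets, each exactly once.
* Rejection reads the ±100 µV criterion as absolute post-baseline
  amplitude at any sample of any channel (a peak-to-peak > 200 µV reading
  is available via `mode="peak_to_peak"`).
* ORN windows are fixed constants per group label (250–350 ms young,
  350–550 ms elderly) with an override — in practice such windows are set
  by visual inspection of grand averages, which a simulation cannot
  reproduce.
* Peak latency is the polarity extremum of the *averaged* waveform within
  the window (no single-epoch latencies). Zero-noise template recovery
  through the full chain is exact to < 0.5 µV; the residual comes from the
  0.5 Hz high-pass removing a small amount of the Gaussian bump's
  low-frequency energy (≈ 0.1–0.3 µV undershoot).
* The permutation paired t-test flips signs of per-subject differences,
  with p = (1 + #{|t_perm| ≥ |t_obs|})/(n_perm + 1).

## Statistics (`sfgsim.behavior`)

* **d′ correction:** every count is pulled half a trial toward chance
  (rate = (count ∓ 0.5)/N), which maps 0 → 1/(2N) and 1 → 1 − 1/(2N) and
  keeps all z-transforms finite. Applied to all rates, not only extremes,
  so perfect and near-perfect scores are treated continuously.
* **Split-plot ANOVA** exploits the 2-level within factor exactly:
  between-subjects effects are tested on per-subject condition means,
  within and interaction effects on per-subject condition differences,
  via effect-coded OLS. For unbalanced groups this yields Type III tests
  (the within main effect is the unweighted mean of group difference-
  means). With balanced groups the F, p and η_p² agree with
  `pingouin.mixed_anova` to machine precision (verified in tests); with
  unbalanced groups the within effect differs from weighted-means
  computations by design. Sphericity is not an issue (2 within levels).
  Degenerate designs with zero residual variance return F = 0 or ∞ rather
  than erroring.
* **Tukey–Kramer:** q = |m_i − m_j| / √(MS_err/2 · (1/n_i + 1/n_j)),
  p from the studentized-range distribution; validated against a numeric
  double-integration of the range CDF and the k = 2 identity q = √2·|t|.
* **Correlations:** Pearson r with t-transform p and Bonferroni
  adjustment min(1, m·p).

## Protocol orchestration (`sfgsim.protocol`)

Sub-streams are derived as `SeedSequence((master, participant, stage))`,
so no stream is shared across participants or stages and every run is
bit-reproducible from the master seed. Training follows the published
block structure (6 × 10 trials, coherence 18 → 8 step −2, repeat from the
last >50%-accuracy block until one of the last three blocks exceeds 50%,
with a configurable repetition cap defaulting to 10 before a non-learner
flag). The main task uses the 800-trial blocked schedule. Main-task
responses are generated from the symbolic stimulus parameters (the
parametric observer needs no rendered audio); WAV rendering is optional.

## Problem sizes

The packaged checks use 50 observers × 2000 probe trials for the staircase
operating points and 20 seeds × 150 figure epochs per group for ERP
latency recovery — sizes at which the Monte Carlo error of the reported
means/medians is well below the tolerances being checked (≈ 0.5 pp and
≈ 2–3 ms respectively), while a full run completes in well under a minute
on a single CPU. The full-cohort protocol simulation defaults to the
design's 49 listeners and 800 trials each.

## Known limitations

* The observer is stationary: no learning, fatigue, attention lapses
  beyond the constant lapse rate, or RT–accuracy coupling.
* The false-alarm rate is fixed rather than criterion-derived, so
  individual differences in response bias are not modeled.
* EEG realism is deliberately minimal (see above); source-space analyses
  are out of scope, and the permutation test is provided at sensor level.
* Stage 2's convergence flag is usually false under the default level
  grid (see QUEST section); this mirrors the stopping rule's behavior on
  fine level spacings rather than an estimation failure.
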