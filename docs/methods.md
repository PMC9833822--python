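# Methods

This note documents the statistical model behind `vocaldyad`, the choices
made where the design was genuinely open, and what the synthetic validation
does and does not establish.

## Data model and preprocessing

The analysis unit is a 60 s epoch on a uniform session grid; all series are
indexed 0-based with half-open intervals. Arousal per participant is a
composite of heart rate (+), heart-rate variability (−) and movement (+):
channels are sign-oriented so higher always means more aroused, z-scored
over their own valid epochs (sample SD, ddof = 1), averaged across whatever
channels are observed at each epoch (an epoch is valid when at least one
channel is), and the average is re-z-scored. All z-scoring baselines are the
*valid* (home-and-awake) epochs, since every analysis is restricted to them;
"chance = 0" therefore means "that participant's mean analysed arousal".
Validity masking is destructive and monotone: masked epochs become NaN,
statistics are recomputed on survivors, and masking never resurrects an
invalid epoch.

Because arousal is strongly autocorrelated, event-locked *trajectory*
analyses use residuals of a per-participant OLS AR(1) fit
x[t+1] = a + b·x[t], estimated only on consecutive valid pairs (gaps break
pair formation; the first epoch of each valid run has no residual and
becomes invalid), re-z-scored. Stability and coupling analyses use the
non-residualised composite: windowed lag-1 autocorrelation *is* the
stability quantity, and residualising first would remove it by
construction. ROC and peak analyses likewise use the composite, since they
concern arousal level, not innovation.

## Event-relative statistics

* **Likelihood profiles.** Relative-time bins are 2 min wide with edges at
  odd minutes, −21 … +21 (21 bins; the centre bin is [−1, 1) and the
  canonical "1–3 min after" window is a bin). The outermost bins reach
  21 min so that the ±20 min range is fully tiled by equal bins. For a
  reference event at epoch t and bin [a, b), the indicator is whether ≥1
  target event falls in epochs [t+a, t+b); a bin contributes for an event
  only if at least one of its epochs is observable (in-session and valid).
  In self-contrasts the reference epoch itself is excluded as a target
  ("another vocalisation").
* **Trajectories.** Mean arousal at 1 min lags −20…+20; lags with no
  contributing observation are NaN, never 0. Events near session edges
  contribute only their observable lags — no padding or imputation.
* **Peaks.** An epoch is a peak when its value strictly exceeds the
  (100−pct)th percentile (linear interpolation) of that participant's valid
  values; pct ∈ {5, 10, 20}, default 10. Strict exceedance means values
  tied exactly at the threshold are not peaks, so for n distinct values the
  peak count is ⌊n·pct/100⌋ or ⌈n·pct/100⌉.
* **Windowed stability/coupling.** Windows of W = 10 epochs shifted by
  S = 5; a window's statistic is undefined (NaN) below min_valid = 5 usable
  pairs/epochs — a majority-of-window rule chosen because silently
  computing correlations on 2–3 points would be noise. Coupling detrends
  each side by an OLS line over its own valid epochs before the Spearman
  rank correlation (average ranks on ties) over jointly valid epochs.
  Event alignment takes the window whose centre (start + W//2) is nearest
  the lagged epoch, earlier window on ties.
* **Quartile splits.** Events are ranked per participant by the
  vocaliser-side arousal at the event epoch (stable tie-break on epoch
  index) and cut into four near-equal groups; participants need ≥8 usable
  events. Per lag, a one-way ANOVA across the four groups runs on
  participant-level group means.

## Inference

Group inference is at the participant level throughout: per-participant
summaries (likelihoods, trajectory means, AUCs) enter Mann-Whitney U tests
against matched controls or a chance constant, with the Hodges-Lehmann
estimate (median of all n·m pairwise differences) as the effect size. The
exact two-sided p is used when the combined sample is ≤ 20, computed by
tie-aware enumeration of all label assignments (a subset-sum dynamic
programme over doubled mid-ranks — equivalent to full enumeration but
polynomial); larger samples use the tie-corrected normal approximation.

Matched controls place as many pseudo-events as real events uniformly
without replacement on eligible epochs — valid, no vocalisation by either
partner, and not a reference epoch — and repeat the draw (default 1000
repetitions), averaging the statistic across repetitions. Eligibility
excludes *both* partners' vocalisation epochs so the same control sets are
reusable across within- and cross-partner contrasts.

Temporal multiple comparisons are corrected with permutation-based
clustering: per bin, a signed tie-corrected Mann-Whitney z (no continuity
correction); bins with two-sided p < cluster_alpha (default 0.05) form
maximal runs of contiguous, same-sign bins scored by cluster mass Σ|z|;
the null distribution of the *maximum* mass comes from within-participant
condition-label swaps (n_perm = 1000 by default), giving
p = (1 + #{null ≥ obs}) / (n_perm + 1) — never exactly zero. Comparisons
against the chance level 0 use the same machinery with an all-zero control
and sign-flip permutations. The quartile ANOVA variant forms clusters from
per-bin F with p < cluster_alpha, scored by ΣF, with group labels permuted
within participants (one permutation per participant, shared across bins,
preserving temporal structure).

ROC AUC is computed by thresholding at every unique value (classification
strictly above threshold) and trapezoid integration, which equals the
rank-sum probability-of-correct-ordering with ties counted ½; the test
suite verifies this equivalence to 1e−12.

## The synthetic generator

The generator is a forward model of the structures the analyses assume:

* Arousal: bivariate AR(1),
  a_t = Φ a_{t−1} + ε_t, Φ = [[φ_inf, κ_c→i], [κ_i→c, φ_cg]], ε ~ N(0, σ²I),
  stationarity enforced (spectral radius < 1), 50 burn-in epochs, output
  z-scored over valid epochs. Default φ_inf = 0.7, φ_cg = 0.6, σ = 1.
* Events: per epoch, speaker and category, an event fires with probability
  expit(β₀ + β_self·z_own + β_partner·z_partner + γ·[own event within the
  last k epochs]), evaluated on arousal standardised by its stationary SD;
  events fire only on valid epochs, at most one per speaker per epoch
  (category precedence cry > speech-like > other, mirroring how a 5 s
  snapshot is coded once). γ (default preset 0.8, k = 3) produces the
  observed temporal clustering of vocalisations.
* Feedback: infant cries/speech-like events add a boxcar impulse to infant
  arousal for impulse_epochs = 5 subsequent epochs (cries negative,
  speech-like positive), so the cry-vs-speech post-event contrast is
  recoverable.
* Masking: alternating valid/invalid blocks with geometric lengths (mean
  valid block 30 epochs), mimicking naps and outdoor periods rather than
  i.i.d. dropout.
* Sampling: a vocal on-interval is detected in epoch e iff it overlaps the
  snapshot [60e, 60e+5); label from the earliest-starting overlapping
  interval.
* Seeding: one master seed; mask, arousal and event streams are spawned
  from it deterministically, so identical parameters reproduce a dyad
  bit-for-bit.

The `paper_like` preset encodes a realistic day: 440 epochs (~7.3 h) with
half valid (~220 analysable epochs), infant vocalising strongly contingent
on own arousal (β_self cry 1.2 > speech-like 0.8), caregiver vocalising
driven mostly by infant arousal (β_partner 0.6 ≫ β_self 0.1), and baseline
rates set once so that cries are ~⅓ of infant cry+speech events (matching
reported category proportions; absolute per-hour rates are not reported
anywhere, so total rates — ~0.2 infant and ~0.17 caregiver events per valid
epoch — are a fixed design choice of this package).

What the generator does **not** emulate: acoustic waveforms, affect or
intensity beyond categorical labels, circadian structure, movement
artefacts, sensor loss correlated with behaviour, or caregiver-initiated
soothing dynamics beyond linear cross-coupling. Passing tests therefore
show that the estimators recover the modelled dependencies at realistic
sizes and are calibrated under the modelled null — not that real recordings
satisfy the model.

## Validation experiments and problem sizes

The validation suite runs at sizes chosen to give each experiment adequate
Monte-Carlo resolution while keeping the whole suite a few minutes long:

* Null ROC: 200 dyads × 240 valid epochs; mean AUC within 0.5 ± 0.02.
* Cluster calibration: 500 exchangeable-null simulations (20 participants ×
  20 bins, 200 permutations); family-wise false-positive rate in
  [0.03, 0.08] at α = 0.05.
* Effect recovery: β_self(infant, speech-like) = 1.5; 100 cohorts of 20
  dyads; a significant cluster containing lag 0 in ≥90% of cohorts.
* Coupling recovery: κ_i→c = 0.5 vs 0 with φ = (0.8, 0.3), 50 dyads per
  arm, one-sided Mann-Whitney p < 0.01. The directional fast-caregiver
  regime is deliberate: with *symmetric* lagged coupling, within-window
  linear detrending removes the shared slow component and leaves the
  anti-phase fast component, driving the windowed zero-lag statistic
  negative — a real property of detrended short-window synchrony indices
  worth knowing when interpreting them. Relatedly, the statistic carries a
  small positive bias (~+0.01) even for independent partners, because
  detrended smooth series share a deterministic residual position profile;
  real-vs-control designs cancel it.
* Sparse-sampling fidelity: 50 dyads, slow infant arousal (φ = 0.95)
  driving smooth long-range clustering; events dressed as 5–40 s bouts with
  onsets anywhere in their epoch (bouts may spill into the next minute).
  Rank correlation ≥ 0.8 between the mean likelihood profile from true
  bout onsets and from duty-cycled detections. The ground truth counts each
  bout once (as a coder of continuous audio would), while the duty-cycled
  route sees ~30% of bouts, at most once each.

## Numerical conventions and degenerate inputs

Sample SD (ddof = 1) everywhere; percentile by linear interpolation;
undefined statistics propagate as NaN and are excluded from means — they
never silently become 0. Constant channels, all-invalid masks, empty event
sets, too-few pairs/participants and non-stationary simulator parameters
raise typed errors (`ZeroVarianceError`, `EmptyDataError`,
`InsufficientDataError`, `ParameterError`). Cluster scans treat NaN bin
statistics as sub-threshold, so undefined bins break cluster contiguity.
Pipeline outputs are written with fixed float formatting and sorted keys;
a rerun with the same configuration and seed is byte-identical.

## Known limitations

* Incomplete dyads (one partner's arousal missing) are skipped by the
  pipeline loader with a warning rather than retained for individual-level
  analyses; library functions accept single participants directly.
* The AR(1) residualisation assumes a single homogeneous regime per day;
  regime switches (sleep-adjacent drowsiness) are only handled through
  masking.
* The exact Mann-Whitney branch switches to the normal approximation above
  a combined n of 20; for cohort-level tests (n ≥ 8 per arm) this matches
  standard practice but is an approximation.
* Likelihood-profile bins at integer epochs make the centre bin [−1, 1)
  cover lags −1 and 0 (not +1); bin labels state their half-open ranges.
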