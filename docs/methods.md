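# Methods

This note documents the models, estimators, parameter choices and known
limitations of `doceeg`. The package re-implements, as a tested pipeline,
a two-step biomarker analysis of resting-state clinical EEG in patients
with disorders of consciousness (DoC): step 1 screens quantitative EEG
(qEEG) and functional-connectivity measures for sensitivity to etiology
(traumatic vs. nontraumatic brain injury) and to 6-month clinical outcome
(improved vs. nonimproved on the Glasgow Outcome Scale, ΔGOS ≥ +1);
step 2 feeds the surviving biomarkers to a leave-one-subject-out
diagonal-covariance linear discriminant to predict outcome per etiology
stratum.

## Preprocessing

Raw 19-channel 10–20 recordings are resampled to 500 Hz (polyphase,
anti-aliased; the 1024 → 500 Hz ratio is non-integer, so output length is
guaranteed only to ±1 sample) and bandpassed to 1–30 Hz with a
forward–backward order-6 Butterworth filter. Zero-phase filtering is a
hard requirement here: any phase distortion would bias the phase-lag
connectivity estimator downstream. The stop-band contract (≥ 20 dB
relative to the passband) is tested at 0.2 Hz and 40 Hz.

The conditioning chain is idempotent on content away from the filter's
transition bands (re-filtering a mid-band tone changes it by < 1e-6
relative RMS); broadband signal energy close to the 1 Hz and 30 Hz edges
is attenuated again on a second pass. This is an unavoidable property of
any realizable bandpass and is the reason the idempotence test uses
mid-band content.

Artefact rejection is a two-pass rule with an auditable log:

1. **Absolute pass** — drop epochs whose peak-to-peak amplitude on any
   channel exceeds 500 µV (default).
2. **Deviation pass** — per channel, compute each epoch's largest
   absolute deviation from the channel mean; drop epochs whose statistic
   lies more than 3 SD above the mean of that statistic across retained
   epochs, and iterate to convergence. The criterion is applied to the
   *epoch-level* amplitude statistic, not to raw samples: individual
   samples of bandlimited noise exceed 3 SD in essentially every 1-s
   epoch, so a literal per-sample rule would reject everything, whereas
   the epoch-peak statistic is tightly concentrated unless an artefact is
   present. Constant data (zero variance) can flag nothing by
   construction.

Epochs are 1 s for qEEG, coherence and mutual information, and 2 s for
the wavelet-based wPLI (edge margin for the wavelet support). Every epoch
is linearly detrended per channel.

## qEEG measures

The spectrum is the mean of per-epoch, per-channel Hann-tapered
periodograms (µV²/Hz), restricted to 1–30 Hz, then z-scored across
frequency bins. z-scoring across bins makes the dominant frequency and
band summaries invariant to overall amplitude scale. A Parseval check
(band-integrated power ≈ band variance within 10%) guards the estimator.

* **Dominant frequency** — the frequency of the global maximum of the
  z-scored spectrum; ties break toward the lower frequency.
* **Band power** — mean z-power in delta 1–3, theta 4–7, alpha 8–13,
  beta 14–30 Hz; band boundaries are placed midway between the printed
  integer edges (3.5 / 7.5 / 13.5 Hz) with a boundary bin assigned to the
  lower band, so every retained bin belongs to exactly one band.
* **Permutation entropy** — ordinal patterns of order m = 3 at lag 1
  (a configurable default; the order/lag is not dictated by the source
  analysis), pooled over epochs per channel; Shannon entropy normalized
  by log m! to [0, 1]. Ties between equal samples break by order of
  occurrence (stable sort), the standard convention; ties have measure
  zero for continuous data.
* **Mean amplitude** — the mean *absolute* value of the detrended signal.
  The plain mean of a detrended signal is ~0 by construction, so the
  rectified mean is the scale-informative reading of "mean amplitude".

## Connectivity

All three estimators run on surface-Laplacian-referenced signals (each
channel minus the mean of its 10–20 nearest neighbors; the adjacency
table ships versioned as `10-20-nn-v1`). The Laplacian suppresses shared
volume-conducted activity, which is also how the "partial" character of
the coherence estimator is realized: pairwise magnitude coherence on
Laplacian signals, with the spatial filter supplying the removal of
common neighboring sources.

* **wPLI** (weighted phase lag index) at the subject's dominant
  frequency: complex Morlet time–frequency data (6 cycles, Gaussian
  envelope truncated at ±2.5 SD, frequency-domain convolution) on 2-s
  epochs; samples within half a wavelet of an epoch edge are excluded.
  wPLI = |E[Im Sxy]| / E[|Im Sxy|] pooled over epochs and retained
  samples, with a relative-tolerance guard returning 0 when Im Sxy is
  zero to round-off (identical or purely zero-lag-coupled signals). When
  the estimated dominant frequency is so low that the 6-cycle wavelet
  cannot fit a 2-s epoch, the cycle count is reduced (floor 3) rather
  than dropping the subject — exclusion would bias cohorts against
  slow-EEG patients.
* **Surrogate threshold** (optional, per subject): the null is built by
  circularly time-shifting each channel's TF series independently within
  every epoch (spectra preserved, cross-channel phase relations
  destroyed); observed pair values at or below the null's 95th percentile
  are zeroed. Thresholding is reported for single-subject network
  analyses; the cohort-level screening studies use unthresholded ROI
  means, whose cost is a fraction of the surrogate ensemble's.
* **Coherence** — epoch-averaged cross-/auto-spectra with Hann taper and
  zero-padding ratio 8 (finer bin grid for the at-dominant-frequency
  reading); full-band mode averages per-bin coherence over 1–30 Hz. With
  K epoch averages the estimator has a known positive bias of roughly
  1/K for independent signals; the null tests budget for it.
* **Mutual information** — amplitude histograms with 10 equal-width bins
  per channel spanning that channel's observed range (a
  Freedman–Diaconis-derived bin count is available as an option);
  MI = H(X) + H(Y) − H(X,Y) in bits, clipped at 0. Constant channels get
  MI 0 with a warning.

Matrices are 19×19, symmetric, diagonal 0. ROI summaries average five
electrode-pair sets — left/right frontoparietal ({Fp1,F3,F7}×{P3,T5} and
mirror), frontal interhemispheric ({Fp1,F3,F7}×{Fp2,F4,F8}), central
interhemispheric ({T3,C3}×{C4,T4}), posterior interhemispheric
({P3,T5,O1}×{P4,T6,O2}) — with midline electrodes excluded; the global
index is the mean of the five ROI values. The electrode membership is a
declared, configurable choice (a standard hemispheric split of the
montage); the source analysis names the ROIs without listing electrodes.

## Group statistics (step 1)

Scalar qEEG measures: one-way ANOVA between groups, or ANCOVA with age
as covariate for the etiology factor (the etiology groups differ in age).
Connectivity measures carry a five-level within-subject ROI factor and go
through a split-plot mixed model:

* between-subjects stratum = OLS AN(C)OVA on subject means (Type III
  group effect; exactly the classical split-plot between-stratum F);
* within-subject stratum = ROI and ROI×group sums of squares by model
  comparison, with Greenhouse–Geisser ε from the pooled within-group
  covariance applied to the degrees of freedom. With a covariate, ROI ×
  covariate regressors absorb covariate-dependent ROI slopes; the
  covariate-free path is cross-checked against `pingouin.mixed_anova` in
  the test suite (F, ηp² and ε agree).

Planned contrasts use pooled-variance t-tests with a bootstrap p-value
(groups recentered to a common null, resampling within groups, add-one
smoothing) plus a percentile CI of the mean difference. Effect sizes are
ηp² = F·df1/(F·df1 + df2) and pooled-SD Cohen's d. Shapiro–Wilk screens
normality; Mann–Whitney U (exact for small tie-free samples, tie-corrected
normal approximation otherwise) covers ordinal contrasts. A measure is
"selected as biomarker" when its group effect is significant at α = 0.05;
no multiplicity correction is applied across the biomarker family at
step 1, matching the screening design.

## Outcome classification (step 2)

The classifier is a diagonal-covariance linear discriminant ("diagLinear":
both classes share one pooled diagonal covariance; feature correlations
are fully discounted; no coefficient thresholding), with class priors
taken from the training fold. The positive class is *nonimproved* —
sensitivity counts nonimproved patients correctly flagged. Leave-one-
subject-out cross-validation standardizes features and recomputes priors
inside each training fold, so nothing leaks from the held-out subject;
predictions are provably invariant to affine feature rescaling and row
order. "Stepwise" selection is an exhaustive search over all non-empty
subsets of the candidate pool (dominant frequency, global wPLI, MI,
coherence → 15 subsets), ranked by LOO accuracy with ties broken by
balanced accuracy, parsimony, then lexicographic order; a forward-greedy
mode exists for larger pools. A maximum-likelihood logistic regression
runs the same protocol as a control, falling back to a ridge penalty
(1e-4) on perfect separation. ROC curves sweep the pooled LOO
discriminant scores. Chance level is estimated by label-permutation
nulls; note the familiar LOO pessimism — null accuracy sits slightly
below the majority-class rate because the held-out subject lowers its own
class prior.

## Synthetic cohorts

The generator produces the statistical structure each estimator is
designed to detect, not biophysically realistic EEG:

* per-channel 1/f background noise (10 µV RMS at gain 1);
* a narrowband Gaussian oscillator (σ = 0.25 Hz) at the subject's
  dominant frequency, at SNR 2.25 (oscillator/background power), enough
  for the spectral peak to clear the 1/f floor after z-scoring;
* lagged coupling on five designated driver→receiver pairs (one per
  ROI): the receiver's oscillation is mixed as
  √(1−c²)·own + c·(driver delayed a quarter cycle), so wPLI grows
  monotonically with c and reaches ~1 at c = 1, while the quarter-cycle
  lag keeps instantaneous correlation — and hence histogram MI — near
  zero. A zero-lag control mode exercises wPLI's volume-conduction
  discount;
* a shared broadband source mixed into the posterior electrodes with
  alternating-sign gains (a dipolar-like scalp pattern). Sign
  alternation is essential: with same-sign gains the surface Laplacian
  subtracts the source almost entirely and MI barely responds; with
  alternating signs the source survives referencing and drives MI and
  coherence at zero lag (invisible to wPLI);
* artefact epochs (square pulse + drift, 5–6× the background SD) at a
  5% rate, for the rejection stage to find.

Cohort structure follows the reference study's composition (15 TBI,
18 non-TBI). Group effects are injected on the generative parameters:
dominant frequency 4.0 vs 6.0 Hz (SD 0.8, clipped to ≥ 2.5 Hz so a
wavelet fits a 2-s epoch), coupling 0.25 vs 0.75 (SD 0.12) for TBI vs
non-TBI, and shared-source gain 0.4 vs 1.6 (SD 0.3) for nonimproved vs
improved. These are deliberately strong standardized shifts (≈ 2 SD or
more on the parameter scale): the published analysis reports directions,
not generative magnitudes, and the replication studies are specified to
detect the pattern reliably at a 33-subject cohort. The improved
fraction defaults to a single scalar (0.4) applied to both etiology
groups: per-group fractions would correlate outcome with etiology and
leak etiology-linked markers into the outcome screen, a confound the
synthetic design deliberately avoids (a per-group pair can still be
configured). Ages and GCS values are drawn per group from the reference
summary table; GOS pairs are assigned consistently with the outcome
label (improved ⇔ ΔGOS ≥ +1). All draws descend deterministically from
one master seed.

What passing the synthetic studies does *not* show: robustness to real
electrode artefacts (EMG, ocular), non-stationarity, volume-conduction
geometry beyond the nearest-neighbor approximation, medication effects,
or realistic lesion physiology. The generator has Gaussian amplitude
structure, so the histogram-MI estimator sees mainly linear dependence.

## Problem sizes in the replication studies

The replicate study runs 50 independent 33-subject cohorts at 60-s
recordings (the package's standing test length; the clinical default of
20 min is configurable), executes the full pipeline per subject, and
scores the step-1 screen against the expected pattern — exactly
{dominant frequency, wPLI} selected for etiology and exactly {MI,
coherence} for outcome among the four headline measures. Step-2 LOO
accuracy on the first replicate is compared with the 95th percentile of
a 200-permutation label null per etiology stratum. Null calibration uses
1000 bootstrap-test replicates and 400 mixed-model replicates on directly
simulated Gaussian feature tables (no EEG synthesis needed there); 400
rather than the minimal 50 keeps the binomial noise of the empirical
rejection rate well inside the [0.03, 0.07] acceptance band.

## Numerical choices and degenerate inputs

* wPLI returns 0 when E|Im S| is zero to round-off (guard for identical
  / zero-lag signals).
* Rejection pass 2 skips channels whose reference statistic has zero
  variance (constant data).
* MI for a constant channel is 0 (warned); marginal entropies are
  available separately as the self-information diagonal analogue.
* Mann–Whitney switches from the exact to the tie-corrected asymptotic
  distribution at combined n > 25 or in the presence of ties.
* Single-class classification input, training folds with < 2 members of
  a class, empty feature subsets, and cohorts with < 4 subjects per
  stratum are refused explicitly rather than degrading silently.
* EDF output uses 16-bit physical scaling per channel; round-trip error
  is bounded by ~1/65535 of each channel's range.
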