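# doceeg

EEG biomarkers of etiology and clinical outcome in disorders of
consciousness (DoC), from standard 19-channel clinical recordings.

Patients surviving severe acquired brain injury in an unresponsive
wakefulness syndrome or minimally conscious state are hard to assess
behaviorally, yet rehabilitation decisions hinge on their prognosis.
Resting-state EEG — cheap, bedside, routinely acquired — carries usable
prognostic signal. `doceeg` implements a two-step analysis of that
signal for clinicians and methods researchers:

1. **Biomarker screening.** From each subject's cleaned recording the
   package computes four qEEG measures — z-scored band power (δ 1–3,
   θ 4–7, α 8–13, β 14–30 Hz), dominant frequency, permutation entropy,
   mean amplitude — and three functional-connectivity estimators on
   surface-Laplacian-referenced signals, each a 19×19 electrode-pair
   matrix summarized over five regions of interest:
   * weighted phase lag index at the individual dominant frequency,
     wPLI = |E[Im Sxy]| / E[|Im Sxy|], which discounts zero-lag
     (volume-conducted) coupling;
   * magnitude-squared coherence |⟨Sxy⟩|² / (⟨Sxx⟩⟨Syy⟩) (pad ratio 8);
   * histogram mutual information MI = H(X) + H(Y) − H(X,Y) (10 bins,
     bits).
   Measures are screened for group effects (etiology TBI vs non-TBI,
   outcome improved vs nonimproved, where improved means a Glasgow
   Outcome Scale gain of ≥ +1 between 1 and 6 months) with mixed
   ANOVA/ANCOVA (ROI as within-subject factor, Greenhouse–Geisser
   correction, age covariate), bootstrap t contrasts, ηp² and Cohen's d.
2. **Outcome classification.** The selected biomarkers feed a stepwise
   diagonal-covariance LDA ("diagLinear", shared pooled diagonal
   covariance, fold-frequency priors) under leave-one-subject-out
   cross-validation, per etiology stratum, with a logistic-regression
   control and full confusion/ROC reporting. Positive class =
   nonimproved.

Because the underlying clinical recordings cannot ship with the code, a
first-class synthetic-cohort generator produces 19-channel recordings
with the exact statistical structure the pipeline detects (1/f
background, narrowband dominant-frequency oscillator, quarter-cycle
lagged coupling for wPLI, a zero-lag shared source for MI/coherence,
artefact epochs, and configurable group effects), so every stage is
testable end to end. See `docs/methods.md` for the model details.

## Worked example

Simulate the default cohort (15 TBI / 18 non-TBI, 60-s recordings) and
run the whole study:

```bash
doc-eeg run-all --out out --seed 7
```

which prints

```
step1 etiology: selected ['dominant_freq_hz', 'peen_mean', 'wpli', 'zpsd_beta', 'zpsd_delta', 'zpsd_theta']
step1 outcome: selected ['amp_mean_uv', 'mi', 'pcoh', 'peen_mean', 'zpsd_beta']
step2 TBI: accuracy 0.933
step2 nonTBI: accuracy 1.000
```

Reading the output: the etiology screen flags the dominant frequency
(F(1,30) = 31.4, ηp² = 0.51, age-adjusted) and wPLI (F(1,30) = 51.7,
ηp² = 0.63) — the generator injects a slower dominant rhythm and weaker
phase coupling in the TBI group, and the spectral measures co-vary with
the shifted rhythm. The outcome screen flags MI and coherence, the two
estimators driven by the shared source injected into improved subjects.
Step 2 then classifies 6-month outcome within each etiology stratum; on
this seed the best subset is the global coherence alone, with LOO
accuracy 93.3% (sensitivity 88.9%, specificity 100%) in the TBI stratum
and 100% in the non-TBI stratum. Per-subject features land in
`out/features.csv`, connectivity matrices in `out/matrices/`, reports in
`out/step1_*.json` / `out/step2_*.json`, and `out/provenance.json` pins
the config hash and seeds; rerunning with the same seed reproduces every
file.

The same stages are available piecewise (`doc-eeg simulate`,
`preprocess`, `features`, `screen`, `classify`) and as library calls
(`doceeg.generate_cohort`, `doceeg.preprocess`, `doceeg.qeeg_features`,
`doceeg.wpli_matrix`, `doceeg.screen_features`, `doceeg.lda_loo`, ...).
Real EDF directories are processed with
`input_mode="edf_directory"` and a `cohort.csv` of clinical rows.

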