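# Methods

This note documents the models, numerical choices and limitations behind
`frustmi`: what is computed, under which assumptions, and what the synthetic
cohort does and does not establish about real EEG.

## Preprocessing and windowing

Continuous records are processed in a fixed order: per-channel mean removal
over the whole record (baseline correction), an IIR notch at the powerline
frequency (default 50 Hz, quality factor 30), then a 4th-order Butterworth
bandpass (default 1–40 Hz). Both filters run forward–backward
(`filtfilt`), so they are zero-phase and event latencies are preserved. The
cutoffs are the conventional MI-EEG choices; the filter family and order
are this package's choice, made for flat passband response and modest edge
transients.

Trials are segmented into sliding windows of 3000 samples with step 100 (at
the nominal 1000 Hz sampling rate: 3 s windows, 0.1 s step), yielding
`floor((L − 3000)/100) + 1` windows per trial; a 4 s trial gives 11
windows. Windows never cross trial boundaries, are mean-removed per
channel, and carry their source-trial identity — the unit of all
cross-validation splits. "Baseline correction" is interpreted as mean
removal at both the record and window stages, since no explicit baseline
interval is part of the protocol.

## FBCSP

CSP solves `Σ_A w = λ (Σ_A + Σ_B) w` on average class covariances. Per
window, the covariance of the band-filtered, mean-removed signal is
trace-normalized (removing per-window amplitude scale — the normalized
log-variance features are invariant to it anyway) and class averages are
shrunk toward the scaled identity. The shrinkage intensity is a
Ledoit–Wolf-style estimate computed from the dispersion of per-window
covariances around the class mean: `α = min(1, mean‖Σ_w − Σ̄‖²_F / (n‖Σ̄ −
μI‖²_F))`. This form uses the window covariances themselves as
observations, which suits covariance-based pipelines where raw samples are
never pooled; α is also settable explicitly. Eigenvectors come from the
generalized symmetric eigensolver, so each filter satisfies
`wᵀ(Σ_A + Σ_B)w = 1` by construction; the returned matrix holds the top
`m` filters (descending eigenvalue) followed by the bottom `m` (ascending),
with column `j` paired to column `j + m`.

The filter bank defaults to the canonical nine 4 Hz bands spanning
4–40 Hz. Multi-class (3-state) problems use one-vs-rest CSP per class with
features concatenated before selection. Feature selection is MIBIF: each
log-variance feature is discretized into 4 quantile bins, its plug-in
mutual information with the label is computed by direct counting, features
are ranked (ties broken by lower index), the top `k_select = 4` are kept,
and the set is closed under CSP pair completion. Defaults `m = 2`,
`k_select = 4` are the standard FBCSP settings; both are configurable.

Implementation note: because `var(wᵀX) = wᵀ Σ w`, fitting and feature
extraction run entirely on per-window covariance tensors. Band filtering
therefore touches the raw signal once per band, and cross-validation folds
re-fit CSP from cached covariances. This is exact, not an approximation.

## Classifiers

Backends are an RBF-kernel SVM (`C = 1`, `γ = 1/(n_features · var)`) with
sigmoid (Platt) probability calibration, or LDA with automatic shrinkage.
The fusion rules need probability outputs, hence the calibration; pairwise
coupling handles the 3-class case. Per classifier, the backend is chosen by
an inner stratified 5-fold accuracy comparison on training data only, with
ties going to the SVM — mirroring per-subject calibration practice. State
labels are assigned from the induced condition (the feedback success-rate
block), not from self-report. Class imbalance is handled by stratified
folds only. A seed is a required configuration field; every stochastic step
derives from it.

The classifier bank holds the 3-class frustration decoder, one MI model per
state trained only on that state's windows, a pooled MI model over all
induced-state windows (baseline 3-1, optionally subsampled), and a
calibration-only MI model (baseline 3-2).

## Decision strategies

Hard switching selects the most probable state's MI model; probabilistic
fusion computes `p_final = Σ_i p_i · M_i(X)`; the baselines pass the window
to the pooled model directly. Tie-breaks are deterministic and documented:
lowest state index for state ties, "left" for MI ties. Fusion operates per
window; trial-level majority voting is available as an optional
aggregation, but window-level accuracy is the canonical score. An optional
entropy-threshold fallback from fusion to the pooled model exists and is
off by default.

## Evaluation

Cross-validation folds are stratified partitions of trials; every window
inherits its trial's fold. This leakage guard matters: windows overlap by
97%, and an unguarded split lets near-duplicate windows appear on both
sides — the test suite demonstrates a nearest-neighbour memorizer scoring
perfectly without the guard and at chance with it.

Band statistics use Welch PSD (1 s Hann segments, 50% overlap), integrated
over the canonical bands Delta 1–4, Theta 4–8, Alpha 8–12, Beta 12–30,
Gamma 30–45 Hz, averaged over channels, compared between conditions by a
pooled-variance two-sample t-test with sign convention
`t = (mean_A − mean_B)/se`. Band-wise p-values are reported raw (an
optional Bonferroni flag exists). Cohort tables report the arithmetic mean
and the population (÷n) standard deviation to two decimals. Precision from
row-normalized cohort confusion matrices assumes equal class priors; a
never-predicted class is flagged rather than propagated as NaN. Paired
comparisons report both the paired t-test and the Wilcoxon signed-rank
test; degenerate difference vectors (all zero, or zero-variance shifts) are
flagged with documented values instead of NaNs. The repeated-measures ANOVA
delegates to statsmodels' `AnovaRM`, with the zero-between-condition-SS
case short-circuited to `F = 0, p = 1`. Separability of a labelled
embedding is summarized by pairwise centroid distances, Fisher's
discriminant ratio in trace form, and a cross-validated logistic-probe
accuracy; zero within-class spread is flagged "separated". Resilience-scale
scoring sums 25 seven-point items; 146–175 classifies as high resilience.

## Synthetic cohort

The generator produces additive-oscillation EEG, not biophysics: a `1/f`
background (unit exponent, 5 µV RMS), mu (10 Hz, 6 µV) and beta (20 Hz,
2.5 µV) oscillations from two lateralized sensorimotor sources over C3/C4
with per-trial amplitude and phase jitter, and band-limited beta (12–30 Hz)
and gamma (30–45 Hz) state components. The study conditions it emulates:

* **Calibration stage**: 100 left + 100 right MI trials (≈4 s at 1000 Hz),
  no state modulation.
* **Induced-state stage**: three feedback blocks at 80/65/50% success
  rate (low/medium/high frustration), default 30 trials per state × MI
  class, with one 7-point Likert rating per block (normal draws with means
  2.1/3.5/4.8 and SDs 0.8/1.4/1.2, rounded and clipped to 1..7).
* **MI physiology**: imagining a hand attenuates the mu/beta source
  contralateral to it (event-related desynchronization); the default depth
  is a 50% power reduction.
* **State physiology**: beta and gamma power rise with frustration
  (multiplicative gains 1.0/1.2/1.35 and 1.0/1.3/1.6), with
  state-dependent spatial profiles — the beta component shifts centrally
  under medium frustration, the gamma component becomes occipital-dominant
  under high frustration. The spatial dependence is essential: a purely
  isotropic gain changes band power (and is what the PSD t-tests detect)
  but vanishes under per-window covariance normalization, leaving nothing
  for spatial filtering to find.
* **State-dependent MI signature**: the ERD depth scales by 1.0/0.75/0.6
  across states (decodability falls with frustration), and its hemispheric
  balance shifts from strictly contralateral (low) to ipsilateral-dominant
  (medium, high). The balance shift is a stylized construction, not a
  physiological claim: mirror-symmetric ERD confines the left/right
  contrast to a single axis, so only sign and magnitude changes along that
  axis can make a pooled decoder structurally suboptimal — which is
  precisely the regime the state-aware strategies exist for. With these
  defaults the pooled model's training signal nearly cancels across
  states, while each state-specific model sees a clean contrast.

Subjects draw from independent child streams of one seed. Frustration
affects the signal from trial start; there are no within-trial dynamics, no
artifacts (EOG/EMG), no volume-conduction head model, and no
non-stationarity across a session. Consequently, passing the cohort-level
recovery tests shows that the pipeline recovers planted band-power and
spatial structure under realistic noise and window correlation — it does
not show that real frustrated users exhibit this particular signature.

## Problem sizes and numerical choices

The acceptance script and the heavy tests run the cohort at desk scale: 12
subjects, 12 trials per state × MI class, 16 calibration trials per class,
4 channels (C3, Cz, C4, Oz), full 3000/100 windowing — about 900 windows
per subject and a few minutes of compute, which is ample for the
cohort-level contrasts being measured; generator defaults are larger.
Statistical null checks use trial counts (not window counts) as the
effective sample size, since windows within a trial are strongly
correlated. The uniformity check for null band-power p-values simulates
groups of 16 two-second windows so that integrated band powers are close
enough to normal for the t-test to be well calibrated. Degenerate inputs
(zero-variance windows, rank-deficient composite covariances, empty
confusion-matrix columns, all-zero paired differences) raise or flag
explicitly rather than producing NaNs.

## Known limitations

* EDF/BrainVision writers cover the plain cases used for round-trips
  (single-record 16-bit EDF without annotations; float32 BrainVision);
  readers, via mne, are general.
* The bank serialization embeds fitted scikit-learn objects by pickling
  into the HDF5 bundle; load only files you wrote.
* Feature selection is independent per task (state vs MI); no sharing.
* No artifact rejection, re-referencing or resampling; recordings are
  assumed clean and at a single rate.
* Online/incremental operation is out of scope; the pipeline is an
  offline analysis framework.
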