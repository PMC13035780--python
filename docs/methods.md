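# Methods

`qeeg` analyzes resting-state EEG from a two-group, two-timepoint stroke
cohort: an experimental group (neuroprotective add-on therapy) and a
control group (standard care), each recorded at baseline (T0) and after a
one-week course (T1). It quantifies the classic electrophysiological
signature of cortical ischemia — excess slow-wave (delta/theta) power,
depressed fast-wave (alpha/beta) power, and reduced signal complexity —
and its normalization under treatment, and relates the EEG changes to the
clinical improvement on the NIH Stroke Scale (ΔNIHSS = NIHSS_T0 −
NIHSS_T1, positive = improvement). Because the corresponding patient
recordings are private, the package ships a calibrated synthetic-cohort
generator with the same statistical structure; everything downstream of
the generator treats its output exactly like patient data.

## Preprocessing

A recording is six 10–20 electrodes (C3/C4 central, P3/P4 parietal, O1/O2
occipital; odd index = left hemisphere) sampled at 1 kHz in microvolts.
The chain is:

1. **Band-pass 1–45 Hz** — 4th-order Butterworth applied
   forward–backward (`sosfiltfilt`), so the phase response is exactly
   zero; phase distortion would corrupt the complexity measures. The
   doubled magnitude response attenuates 50/60 Hz mains and sub-hertz
   drift by more than 20 dB.
2. **Common average reference** — each sample's channel mean is
   subtracted; the referenced channel mean is identically zero.
3. **Epoch selection** — the recording is partitioned into
   non-overlapping 4-s windows starting at t = 0; a window is rejected if
   any channel's peak-to-peak amplitude exceeds 200 µV; the first five
   surviving windows (20 s of signal) are kept, in temporal order.
   Selection is fully deterministic; if fewer than five windows survive,
   the pipeline stops with an explicit error carrying the counts. Manual
   artifact screening and ICA are deliberately out of scope — an
   ICA-cleaned file can be supplied as input.

## Spectral features

Per channel, Welch's method with 1-s Hann windows, 50 % overlap and
constant detrend is applied to each epoch; the five per-epoch PSDs are
averaged before band integration (no window straddles an epoch join), and
normalization happens once, after averaging. Relative band power (rPSD)
is the band's power divided by the total power over 1–30 Hz, for the
canonical bands delta 1–4, theta 4–8, alpha 8–13, beta 13–30 Hz.

**Band-edge convention.** With 1-s windows the frequency grid is 1 Hz and
bins fall exactly on the shared edges 4, 8, 13 Hz. Each bin is treated as
a rectangle of width 1 Hz centred on its frequency, and band power is the
coverage-weighted rectangle sum: an edge bin contributes half its power
to each neighbouring band, the outer bins (1 and 30 Hz) contribute half
to the total band, and nothing is counted twice. Under this rule an ideal
white-noise spectrum yields band fractions equal to the continuous
bandwidth ratios 3/29, 4/29, 5/29, 17/29 — a hard-edged assignment of
whole bins cannot reproduce these, which is why it was rejected.

## Nonlinear features

Both complexity measures are computed per epoch and averaged across the
five epochs (concatenating the epochs would create artificial
discontinuities at the joins that inflate both measures), after
anti-aliased polyphase resampling:

- **Lempel–Ziv complexity.** The epoch is binarized at its median (1
  above, 0 at or below; the median is the dominant convention in the
  EEG-LZC literature and is outlier-robust; the mean is selectable). The
  binary sequence is parsed with the LZ76 exhaustive-history rule
  (scan-and-copy from the extended history plus a one-symbol innovation),
  giving the phrase count c(n); the reported value is the normalized
  complexity c(n)·log₂(n)/n, which tends to 1 for fair-coin sequences and
  to 0 for periodic ones. A constant epoch binarizes to all zeros with a
  degenerate-input warning.
- **Approximate entropy.** Original formulation including self-matches:
  ApEn = Φᵐ(r) − Φᵐ⁺¹(r) with Φᵐ(r) the average log-fraction of
  templates within Chebyshev distance r, m = 2 and r = 0.2·SD of the
  epoch (population SD). ApEn is scale-invariant because r scales with
  the SD; a constant epoch returns 0 with a warning.

**Analysis rates.** LZC is computed at 200 Hz and ApEn at 1000/6 ≈
166.7 Hz. At the native 1 kHz a ≤ 45 Hz signal is oversampled roughly
tenfold: the binarized sequence flips only every dozen samples (normalized
LZC collapses toward 0.2) and consecutive ApEn templates are nearly
identical, while the O(N²) ApEn sum becomes needlessly expensive. The two
rates were fixed once so that the group-level values of the calibrated
simulation fall in the clinically reported ranges (normalized LZC
~0.4–0.6, ApEn ~0.7–1.0); they are configuration fields, not per-dataset
knobs.

Note on interpretation: higher ApEn means *less* predictable dynamics;
in this clinical context an ApEn increase is read as recovery of the
network's dynamic range, not as noise.

## Affected-hemisphere summaries

The analysis targets the hemisphere containing the infarct: electrodes
(C3, P3, O1) for left-sided and (C4, P4, O2) for right-sided infarcts.
Each feature is reported per electrode and summarized as the mean across
the three regions; the alpha/beta power ratio is formed from the
summarized band powers.

## Statistics

Two-sided tests throughout, α = 0.05: paired t within group (T0 vs T1),
pooled-variance Student t between groups at T1 (Welch selectable),
Pearson chi-square without continuity correction for categorical baseline
variables (Yates selectable), and Pearson correlation (p via the
t-transform, df = n−2) between the experimental group's T1 features and
ΔNIHSS. Degenerate inputs (zero-variance differences, both groups
constant) raise rather than return NaN.

Multiple testing uses Benjamini–Hochberg step-up q-values computed within
families. EEG-feature tests form one family per contrast × group —
within-experimental, within-control, between-groups-at-T1 — while the
clinical NIHSS tests and the baseline-comparability tests are separate
families: the correction addresses the multiplicity of EEG features
(bands × electrodes × complexity measures), and pooling a group's null
battery with another group's strong effects would inflate its
false-positive rate through the step-up threshold.

## The synthetic cohort

The generator emulates the *measured* statistical structure of such a
trial; every choice below is visible in `CohortSpec` defaults.

**Single channel.** A channel is a sum over the four bands of
√f_b·[√c·z_b + √(1−c)·s_b], where f_b are target band fractions summing
to 1, z_b is Gaussian noise spread over band b, s_b is a deterministic
sinusoid inside band b, and c ∈ [0,1] is the complexity level (c = 1:
fully spread noise; c = 0: four oscillations). Components are normalized
per realization (Parseval in the frequency domain), so realized band
variances are exact. Three design details matter:

- *Continuous spectral envelope.* Within-band noise is shaped by a
  piecewise-linear density, continuous across band edges with a mid-band
  hump ("tent"). A blockwise-flat density has steps exactly where the
  Welch window's spectral kernel straddles a band edge, which biases
  delta by ~3 percentage points; continuity removes the first-order bias
  and also keeps delta power away from the 1 Hz filter skirt.
- *Estimator compensation.* The reported clinical values are themselves
  Welch-measured, so the generator targets the measured quantity: an
  analytic expectation model (true density convolved with the Hann
  window's power kernel, multiplied by the zero-phase band-pass power
  response, integrated with the coverage rule) is inverted by fixed-point
  iteration so the *expected measured* fractions equal the targets. The
  adjusted weights differ from the targets by a few points at most.
  The model assumes the default analysis settings; with a non-default
  Welch window or band-pass a small residual bias returns.
- *Channel-distinct oscillations.* Each channel's band oscillation is
  offset by a channel-specific 0.2 Hz step (±0.5 Hz around 2, 6, 10,
  21 Hz). Identical tones across channels would be common mode and vanish
  under the average reference; identical frequencies with random phases
  survive as random phasors and add large per-recording band-power noise.
  Distinct frequencies are orthogonal over the recording, so
  re-referencing mixes their power deterministically, like noise.

**Cohort.** 40 subjects per group, two sessions each. Per-subject band
fractions are Dirichlet draws around the group targets (concentration 80,
giving between-subject SDs of ~3.5–5.5 percentage points, matching the
reported group SDs); the three infarct-side electrodes use the "affected"
targets, the other three the "healthy" targets (healthy-hemisphere
targets are set to the control baseline profile — an assumption, since
only the absence of healthy-hemisphere changes is reported). The drawn
per-hemisphere profiles are pre-warped by the inverse of the
average-reference mixing (measured = (27·own + 3·other)/30 for six
equal-power incoherent channels) so that pipeline-measured fractions are
unbiased for the drawn ones. Signals are scaled to 20 µV RMS — clean
resting EEG that sits safely under the 200 µV rejection threshold — and
recordings are 28 s long so the five-epoch selector has two spare
windows, mirroring a protocol that records minutes and selects clean
segments. Optional high-amplitude spikes (rate and amplitude fields)
exist solely to exercise epoch rejection.

**Group calibration.** Affected-hemisphere band-fraction targets are the
reported group means (rows renormalized to sum to 1; as printed they sum
to ~96–101 %). The control group's T1 target equals its T0 profile with
a 0.5-point theta decrease: the printed control T1 row is incompatible
with the same study's inferential claim that no control band change was
significant (with the printed SDs, a 5-point beta shift at n = 40 is
p < 0.001 under any within-subject correlation), and the generator
follows the inferential claims, which are what the qualitative-pattern
checks test. Complexity levels default to 0.2 at baseline and 0.9 for
the treated group at T1.

**Calibration limits.** After average referencing each channel carries
all 24 slightly-detuned oscillations, whose beat structure dominates the
median-binarized pattern; the complexity knob therefore moves
cohort-level LZC/ApEn only weakly (on isolated channels it spans
normalized LZC ~0.27–0.62). The treated group's T0→T1 complexity
increase in the simulation is carried mostly by the spectral shift and
reaches about +15–18 % for LZC and +12 % for ApEn, versus the reported
+40 % and +23 %: T1 complexity cells recover ~9–10 % low. Similarly, only
the alpha/beta-ratio correlation with ΔNIHSS is designed in; LZC and ApEn
have no per-subject variation linked to recovery, so their reported
positive clinical correlations (0.581, 0.524) are not emulated. Worse
than absent, they come out *negative* in the simulation (around −0.4 to
−0.6): a high alpha:beta ratio means relatively less high-frequency
content, hence a lower binarized flip rate and lower LZC/ApEn, so
features tied to ΔNIHSS through the ratio anticorrelate with complexity.
In patients, complexity and recovery presumably covary through
physiology this Gaussian-mixture generator does not contain. Treat the
LZC/ApEn rows of `correlations.csv` on synthetic cohorts as a generator
artifact, not a prediction.

**NIHSS.** Baseline scores are rounded group-specific normals (13.0 ±
3.2 experimental, 12.5 ± 2.5 control) clipped to the 5–20 inclusion
window. ΔNIHSS is linear-Gaussian in the subject's true (drawn)
affected-hemisphere alpha/beta ratio at T1; because integer rounding and
the NIHSS_T1 ≥ 0 clip attenuate correlations, the design slope and
intercept are tuned iteratively inside the generator until the realized
ΔNIHSS hits the target group mean (7.2 / 4.5) and the target correlation
(0.632) against the true feature. The pipeline-measured correlation then
attenuates only by feature-measurement noise, landing near 0.60–0.63 at
n = 40.

**Determinism.** Every subject has an RNG stream keyed by (master seed,
subject index), so identical specs give bit-identical cohorts and
enlarging a cohort leaves existing subjects unchanged.

## What the synthetic cohort does and does not show

The generator reproduces: the measured band-fraction structure and its
group × time differences, between-subject heterogeneity at the reported
scale, hemisphere lateralization, complexity levels in the reported
ranges, the clinical score distributions, and one designed EEG–clinical
correlation. It does not contain: real artifacts (blinks, EMG, electrode
pops) beyond optional amplitude spikes, volume conduction or any
cross-channel correlation beyond the shared reference, non-stationarity
within a session, or non-Gaussian waveform features beyond the band
oscillations. Passing tests therefore validate the *pipeline* — its
estimators, conventions and statistics — under realistic spectra and
effect sizes; they are not evidence about any specific patient
population.

## Numerical and procedural choices

- Welch taper: Hann by default (better sidelobe roll-off); Hamming or
  any scipy window selectable.
- Filter order 4 (per direction); detrend: constant, per window.
- ApEn uses ≤ (not <) in the tolerance comparison and natural logs.
- LZC exposes both raw phrase count c(n) and the normalized value.
- EDF files are written with one-second records, per-channel symmetric
  physical ranges covering the data (round-trip error ≤ one 16-bit
  quantization step), a fixed start date for byte-reproducibility, and
  integer-second durations; reading goes through MNE and converts to µV.
- Statistical engines are scipy/statsmodels (`ttest_rel`, `ttest_ind`,
  `chi2_contingency`, `pearsonr`, `multipletests(fdr_bh)`) behind the
  package's interfaces; the test suite checks them against hand-computed
  and brute-force oracles.
- Problem sizes in the test suite: the qualitative-pattern and
  correlation checks use 20 replicate cohorts of n = 40/group each; the
  null calibration uses 500 replicates at n = 15/group with
  spread-noise-only signals (complexity 1) and no band-pass — under the
  null any estimator bias is common to both groups, so the p-value
  calibration is unaffected while the simulation stays light.

## Known limitations

- The complexity knob is weak at cohort level (see calibration limits);
  treated-group T1 complexity cells recover ~10 % below the reported
  values, and control-baseline LZC runs ~12 % above, the compromise of a
  single analysis-rate calibration.
- The estimator compensation is exact only for the default analysis
  configuration.
- Epoch selection "first five clean windows" is one deterministic
  reading of a protocol that selected stable segments manually; a
  different selection rule would shift nothing systematically for
  stationary synthetic signals but could for real data.
- No missing data handling: the pipeline errors on absent recordings or
  scores rather than imputing (the emulated trial had no loss to
  follow-up).
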