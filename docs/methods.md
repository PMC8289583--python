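# Methods

## Scope and model

`beatboost` implements five-class (N, S, V, F, Q) heartbeat
classification from two-lead ECG: wavelet preprocessing, delineation,
five attributable feature sets, an AdaBoost ensemble of random
forests, and per-class evaluation. A synthetic generator supplies
labeled records with exact ground truth so every stage is testable
offline; this note records the modeling assumptions, parameter
choices, and the limits of what the synthetic results demonstrate.

## Synthetic ECG generator

Each beat is a sum of three Gaussian bumps (P, QRS, T) per lead. A
bump with amplitude *a* (mV), width *w* (s) and center *c* (s relative
to the R peak) has standard deviation σ = w/6, so its ground-truth
boundaries are c ± 3σ — boundary indices are known analytically, which
is the whole point of the model: delineation can be scored to the
sample. Defaults: 360 Hz sampling; class proportions equal to the
per-class beat totals of the MIT-BIH arrhythmia database under the
AAMI grouping (≈82.8/2.5/6.6/0.7/7.3% for N/S/V/F/Q); two leads, lead
B derived from lead A by per-wave scale/sign factors (P ×0.5,
QRS ×−0.7, T ×0.4) to emulate the limb-vs-precordial contrast.

Class templates differ in the features clinicians use: S beats are
premature (mean RR 0.58 s vs 0.80 s for N) with no P wave; V beats
have a wide (0.14 s), tall QRS, inverted T, no P; F beats an
intermediate QRS width with a small (0.12 mV) P; Q beats a low, wide,
atypical complex. Wave amplitudes and widths are jittered per beat
(multiplicative Gaussian, σ = 15% and 8%, clipped to [0.7, 1.3] and
[0.8, 1.2]). The jitter matters: real rhythms vary beat to beat, and
without it each class collapses to a single waveform and any single
scalar feature separates the classes perfectly, which would make
feature-set comparisons meaningless. The clipping keeps the R peak
the per-beat maximum of lead A, preserving the noiseless
fiducial-identity invariant.

RR intervals are drawn per beat from the incoming beat's template,
truncated-normal with a 0.3 s floor (resampled, not clipped) so beats
never overlap. Noise is additive per lead: 0.1 mV baseline wander at
0.3 Hz, 0.02 mV powerline at 60 Hz (a US-style recording), 0.03 mV
white noise. These are moderate, realistic amplitudes chosen once;
`NoiseConfig.none()` gives the noiseless variant used for oracle
tests.

What the generator does **not** emulate: notched/biphasic QRS
morphologies, rhythm context (bigeminy, runs), ectopic-focus
variability within a class, electrode artifacts, or inter-patient
variation. Passing the synthetic benchmark therefore shows the
pipeline is internally correct and discriminates class-level
morphology/rhythm differences under noise — it does not predict
accuracy on clinical recordings, which is split- and patient-
dependent.

## WFDB I/O

Records are written and read in the classic MIT-BIH layout: text
header, format-212 signal file (two 12-bit two's-complement samples
per 3 bytes, channels interleaved, 200 adu/mV gain), and the compact
annotation format (6-bit type code + 10-bit interval words with
SKIP/AUX escapes), using the standard annotation-code table so real
database files parse too. Only format 212 is supported; other formats
raise a named error. Quantization bounds the round-trip error at half
an adu (0.0025 mV).

Beat windows are closed intervals [r−90, r+144] (235 samples per
lead, 0-based); beats whose window crosses a record boundary are
dropped. The annotation-symbol → AAMI mapping follows EC57:
{N,L,R,e,j}→N, {A,a,J,S}→S, {V,E}→V, {F}→F, {/,f,Q}→Q, everything
else excluded. The train/test split is per-beat, stratified by class
(plain random splitting would often leave zero F beats in a 10% test
set); a flag disables stratification. A class with fewer than two
beats goes wholly to training with a warning.

## Preprocessing

*CWT.* Direct evaluation of the transform on the sample grid via FFT
correlation with the dilated, truncated (±8 scales) mother wavelet;
Mexican hat by default. Linearity and the impulse response are exact
to numerical precision.

*Denoising.* Multilevel periodized db6 decomposition, deep enough
that the approximation band lies below 0.7 Hz (level 9 at 360 Hz);
the approximation and the coarsest detail band are zeroed (baseline
wander), and the two finest detail bands are soft-thresholded at the
universal threshold σ√(2 ln n) with σ from the finest band's MAD.
Signals too short to resolve the sub-hertz band skip baseline removal
rather than destroy in-band content. The procedure is nearly
idempotent (second pass changes < 1% RMS) because the targeted bands
are already empty or shrunk after one pass.

*R detection.* Detection function = mean CWT magnitude over four
scales spanning roughly 10–25 Hz (the QRS energy band). Two-stage
thresholding: an adaptive floor of 4× the median absolute detection
value, then rejection of candidates below half the median candidate
height — the second stage suppresses T waves, whose wavelet response
is several-fold weaker than the QRS response. A 200 ms refractory gap
is enforced; candidates are refined to the local signal maximum
within ±40 ms, ties going to the larger amplitude then the earlier
index.

*Delineation.* Around each R peak the signal is Savitzky–Golay
smoothed (~30 ms window) and differentiated. Each wave boundary is
found by walking outward from the wave's steepest flank until the
derivative magnitude drops below 5% of that flank's maximum — a
concrete "near-zero derivative" criterion. For a Gaussian bump this
lands at ≈3.0σ, matching the generator's ±3σ ground truth to within
a sample or two. P waves are searched 200→40 ms before QRS onset, T
waves 80→400 ms after QRS offset; a deflection below 5% of the R
amplitude is flagged undetected rather than fabricated. On premature
beats the previous beat's T wave can intrude into the P window and be
reported as a P deflection; that is a genuine overlap ambiguity, not
corrected.

## Features

Sets A/B are the beat windows verbatim (235 / 470 columns). Set C's
seven intervals are fiducial differences over the sampling rate; the
final beat's RR and any undetected wave produce NaN, imputed at
assembly with the per-record column median and flagged (keeps the
matrix rectangular without dropping beats). Set D integrates
|signal − baseline| over the QRS by the trapezoid rule, baseline =
mean of the PR segment (or the 40 ms before QRS onset when no P was
found), which makes the area exactly offset-invariant. Set E is a
level-4 db6 decomposition of the 235-sample lead-A window, extended
to 240 samples by edge replication so the periodized transform is
exactly orthogonal (Parseval holds on the extended window) and
constant windows keep zero detail coefficients; 240 coefficients per
beat. A 12-level decomposition is meaningful only for whole records,
not 235-sample windows, hence the per-beat level of 4 (configurable).
Sets C/D/E use lead A only (configurable), morphology being the only
set where the second lead adds clearly distinct information.

## Classifier

The boosting recursion is exactly the weighted-error / α / reweight
scheme stated in the README, with three engineering choices:

* **Multiclass extension.** The ±1 formulation generalizes
  SAMME-style: α is kept as ½ ln((1−e)/e), the weight update uses the
  misclassification indicator, and prediction is the α-weighted vote
  with ties broken toward the canonical class order N, S, V, F, Q. On
  binary ±1 problems this reproduces the sign rule exactly (tested by
  enumeration). A one-vs-rest mode is available behind a flag.
* **Clamping.** e is clamped to [1e-10, 1−1e-10] so a perfect base
  learner gets a large finite α instead of an infinite one.
* **Imbalance-aware bootstrap.** Per round, classes smaller than the
  balanced share N/K are included in full; the rest of the bootstrap
  is drawn from the larger classes with probability proportional to
  the current weights. A round with e > 0.5 resets the weights to
  uniform and redraws (bounded at 5 retries, then a training error
  naming the round).

Defaults: 10 rounds, 70 trees per forest (70 was the best-performing
forest size in the experiment grid this package mirrors; the
`sweep-trees` command reproduces that sweep over 20–90), single-thread
forests for deterministic, portable behavior. All randomness flows
from one integer seed through derived substreams (generator, split,
bootstraps, forests), so a run is reproducible byte-for-byte.

## Evaluation

One-vs-rest counts use the standard orientation — FN from the class
row, FP from the class column — which is the orientation consistent
with published per-class tables for this task. Percentages are
rounded half-up to two decimals with exact integer arithmetic
(`decimal`); zero-denominator metrics are reported as undefined, not
0. Published tables occasionally truncate rather than round, so
recomputation tests compare within ±0.02 percentage points.

## Problem sizes

Tests and the acceptance script use desk-scale sizes chosen to keep
the full suite in the low minutes while leaving no stage untested:
200-beat noiseless records for delineation oracles, the default
500-beat noisy record for detection F1, and 3,000 beats for the
end-to-end benchmark (10 rounds × 70 trees, stratified 90/10 split,
≈300 held-out beats). At these sizes the benchmark conclusion —
full attributable combination ≈100%, QRS area alone ≈80–85% — is
stable across seeds.

## Known limitations

* The delineator assumes monophasic waves; biphasic T waves or
  notched QRS would need a multi-flank extension.
* The balanced bootstrap's minority threshold (N/K) is a simple rule;
  extremely skewed mixes might warrant an explicit per-class quota.
* Feature-set E's length depends on the window length and level;
  models are not portable across different segmentation windows.
* WFDB support covers format 212 single-file records only.
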