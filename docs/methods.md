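# Methods

This note documents the models, parameter choices, and numerical decisions
behind `glimpsetrf`, and what the synthetic-data tests do and do not
establish about real recordings.

## Stimulus representations

**Band spectrograms.** A waveform is passed through a bank of 4th-order
Butterworth bandpass filters with logarithmically spaced edges between
50 Hz and 8 kHz (10 bands for TRF regressors, 100 bands for glimpse-ratio
computation), each band's Hilbert envelope is averaged within 10 ms frames
(100 Hz frame rate).  Magnitudes stay **linear**, not dB: the glimpsed/
masked algebra (element-wise min/max and the conservation identity
glimpsed + masked = original) presumes nonnegative magnitudes, and half-wave
rectified derivatives of log values behave qualitatively differently.  A top
band edge at exactly the Nyquist frequency is nudged just inside it for the
digital filter design.

**Edges.** `edge[t, b] = max(spec[t, b] − spec[t−1, b], 0)`, first frame 0.
Glimpsed edges are `min(talker, mixture)`, masked `max(talker − mixture, 0)`;
the mixture representation is computed from the summed signal, not the sum
of talker representations, because envelopes are not additive.

**Glimpse ratios.** A time–frequency cell is glimpsed when
`talker ≥ background · 10^(θ/20)` (magnitude convention; a power convention
`10^(θ/10)` is selectable).  The ratio's denominator counts *all* cells of
the phoneme's interval; restricting it to cells where the talker has energy
is available behind a flag (`denominator="nonzero"`), since the set-notation
definition is ambiguous about zeros.  Cells where talker and background are
both zero count as glimpsed through the `≥` comparison.  Intervals own the
half-open frame range `[round(start·rate), round(end·rate))`.

**Phonetic features.** 22 binary articulatory/acoustic features per ARPABET
phoneme, shipped as a data table reconstructed from standard articulatory
phonology (Chomsky–Halle-style assignments).  With 22 features over 39
phonemes some vowel pairs share vectors (the feature set cannot separate
all diphthongs); the mini-alphabets used by the synthetic generator are
chosen with mutually distinct vectors.

## Banded ridge TRFs

The design matrix stacks lagged copies (0–500 ms, 51 lags at 100 Hz;
−100–600 ms for display fits) of all feature groups; columns are ordered
feature-major, lag-minor.  Each group g carries its own penalty λ_g, and the
minimizer of `‖y − Xw‖² + Σ_g λ_g‖w_g‖²` is obtained by rescaling columns by
1/√λ_g and solving a unit-penalty ridge via one SVD.  For tall problems
(rows > 3× columns) and inside cross-validation the identical minimizer is
computed through the Gram/Cholesky normal equations, which is much cheaper;
an oracle-equivalence test holds both paths to 1e−8 against a direct solve.

Feature columns are z-scored with training-fold statistics *before* lagging
(so printed lambdas are comparable across features); the response is
centered per training fold (intercept).  Zero-padding the standardized
signal at lag edges differs from standardizing lagged copies only within
one lag span of the signal edges.

Cross-validation uses 5 **contiguous** time blocks; test frames within one
lag span of a fold boundary are excluded from scoring, because lagged
copies leak across the boundary.  Accuracy is the Fisher z of the Pearson
correlation per electrode, averaged over folds; correlations are clipped
away from ±1 before `atanh`, and degenerate folds (constant prediction or
response) are recorded as missing.

**Lambda schedule.** The first two groups are tuned jointly on a polar grid
(17 angles in (0, π/2) parameterizing the λ-ratio; radii 10⁻²–10⁵ in
half-decade steps swept through the eigenvalues, so each angle costs one
factorization per fold).  Every later group is tuned one at a time on a
25-point log grid with earlier lambdas frozen; a group's λ is then identical
in every subsequent model and across electrodes, which keeps TRF magnitudes
comparable between electrodes.  Ties break toward larger λ; a boundary
optimum warns.  A table of published regularization values for the original
two-talker iEEG dataset can be loaded instead of tuning
(`lambda_source: reference`).

## Model comparison

**Ablation.** The null model refits with one group removed and identical
lambdas, folds, and lags; Δz per electrode is the baseline-minus-null
accuracy.  The headline p is the hierarchical bootstrap of Δz; a one-sided
paired t across electrodes is reported alongside.

**Shuffled nulls.** Acoustic groups are locally time-shuffled in 500 ms
windows (which preserves local and global statistics), phonetic groups get
a permuted phoneme→feature mapping (consistent per phoneme, so timing and
identity information survive), and word onsets move to a random phoneme
onset within each word.  Per-electrode significance compares the baseline
accuracy against 10 shuffled-model accuracies.  The t statistic uses
prediction-interval scaling `(base − mean)/(sd·√(1 + 1/n))`: the baseline is
a *single draw* compared against a sample, and the unscaled one-sample form
rejects at ≈25% under the null (verified empirically) while this form is
calibrated.  This is a deliberate refinement of the usual practice.

**Threshold sweep.** Phonetic regressors are rebuilt at each glimpse SNR
threshold (default grid −12…+4 dB in 1 dB steps) with lambdas frozen (tuned
once at 0 dB); the mean CV Fisher z per threshold is compared against the
argmax with hierarchical-bootstrap contrasts.

## Group-level statistics

The **hierarchical bootstrap** resamples subjects with replacement, then
electrodes within each sampled subject with replacement (each resampled
subject keeps its own electrode count); the one-sided p is the fraction of
iterates on the null side of the comparison value, floored at 1/N_boot.
TRF **power time courses** average squared weights over features and
electrodes (power, because sites respond with either sign); SEM is over
electrodes.  **Latency** is the lag of the peak of the 2× band-limited
upsampled power curve (5 ms resolution; ties resolve to the earliest peak;
flat curves are undefined).  Anatomical organization is the Spearman
correlation between electrode position (posterior–anterior coordinate, or
distance from the pSTG–mSTG boundary, supplied as precomputed scalars) and
Δz, with significance from hierarchically bootstrapping the correlation.

## Neural preprocessing

Zero-phase first-order 1 Hz Butterworth high-pass; optional nearest-neighbor
re-referencing from an explicit neighbor map (array topology is not
inferred); second-order IIR notches of 1 Hz bandwidth at 60/120/180/240 Hz
(harmonics above Nyquist are skipped with a warning).  High-gamma envelopes:
eight 10 Hz bands spanning 70–150 Hz, 4th-order Chebyshev-II bandpass with
40 dB stopband attenuation (the filter family is standard; order and
attenuation are our choices), Hilbert magnitude, average, polyphase
resampling to 100 Hz, clipped at zero.  Envelopes are z-scored against a
pre-stimulus silence period; electrodes are kept when the pooled-SD Cohen's
D of speech vs silence exceeds 0.2 (strict).  Synthetic pipelines enter
directly at the envelope stage.

## Synthetic data: what it emulates, and what it does not

Talkers are sequences of pseudo-phoneme segments (lognormal durations
50–250 ms, words of 2–6 phonemes) rendered as Gaussian spectral profiles
over log-band index with three lognormal amplitude processes: per-segment
level (sd 10 dB — the phoneme-to-phoneme level variation of natural speech,
and the property that makes each phoneme's glimpse ratio a sharp function
of the threshold near its own SNR), frame-level modulation (2 dB), and
cell-level fluctuation (2 dB).  Symbols share a limited set (≤8) of spectral
profiles, so acoustically confusable phonemes exist and phonetic identity
carries information beyond the spectrogram — without this, phonetic
regressors are linearly absorbed by the spectrogram and ablations cannot
see them.  Mixtures are RMS-matched sums in spectrogram space (waveform
rendering and the audio front end are available for end-to-end tests).

Responses are the encoding model run forward: per electrode, the sum over
encoded groups of the lagged convolution with a ground-truth TRF (Gaussian
bump in lag; per-feature amplitudes; 5 ms latency jitter), plus Gaussian
noise scaled to a target oracle correlation (r ≈ 0.3 in the main presets).
Each group's drive is normalized so its `amplitude` sets its share of the
signal (raw regressor scales differ by orders of magnitude).  Subject-level
structure enters three ways: multiplicative response gain, SNR jitter, and
— in the null preset — *within-subject shared noise* (fraction 0.5) plus
subject-clustered electrode coordinates.  The shared structure matters: with
iid electrodes the hierarchical bootstrap is intrinsically conservative
(its double resampling inflates the bootstrap variance by ~√2), and only
genuinely nested nulls are a fair calibration target.

**Identifiability.** With a small alphabet the 22 feature columns are
collinear (k phonemes span at most k feature dimensions), so ground-truth
phonetic amplitudes are drawn as the minimum-norm representation, in the
standardized metric the ridge estimator uses, of the intended per-phoneme
drive — the only representation any estimator could recover.  The
weight-recovery preset (`stg_like`) uses a 6-symbol alphabet and a
phonetic-only bank for the same reason: acoustic and phonetic groups are
structurally collinear in the generator (phoneme identity fixes the
spectral profile), so per-group truth is only recoverable when the bank is
restricted to the driving groups.  Recovery fits use λ = 3×10⁵, the largest
shrinkage within one standard error of the cross-validated optimum for this
problem class (1-SE rule).

**What passing tests show.** Parameter recovery, calibration, and threshold
recovery on these presets establish that the *pipeline* is correct: exact
conservation identities, solver equivalence, unbiased latency estimation at
realistic SNR, near-nominal type-I error under nested dependence, and
ability to identify the generating glimpse threshold within 1 dB.  They do
not establish anything about real cortex: the generator has no refractory
dynamics, no across-frequency masking asymmetries, no attention state, no
F0 structure, and its phoneme inventory and spectral profiles are
schematic.

## Preset study conditions

| preset | subjects × electrodes | duration | encoded groups (latency) | noise |
|---|---|---|---|---|
| `stg_like` | 7 × 10 | 600 s | glimpsed phonetic (190 ms), masked phonetic (285 ms) | r ≈ 0.3 |
| `hg_like` | 7 × 10 | 120 s | mixture spectrogram (70 ms), glimpsed phonetic of both talkers (110 ms); masked present but not encoded | r ≈ 0.3 |
| `null` | 7 × 10 | 40 s | none | unit noise, shared fraction 0.5 |
| `threshold_recovery` | 6 × 5 | 60 s | glimpsed (40 ms) / masked (120 ms) phonetic at θ\* | r ≈ 0.3 |
| `flat_threshold` | as above, binary (threshold-free) drive | | | |

The nested-null calibration simulation uses 10 subjects × 10 electrodes
with subject sd 1 and electrode sd 2: subject effects strong enough that a
naive electrode-level t test rejects at ≈18%, balanced enough that the
percentile hierarchical bootstrap stays near nominal.

## Problem sizes and numerical choices

Test and acceptance runs use the preset sizes above; the threshold-recovery
check sweeps 17 thresholds × 20 runs per condition at 6×5 electrodes and
60 s, and calibration checks use 200 pipeline runs / 500 bootstrap runs.
Correlations are clipped at 1−10⁻¹² before Fisher transformation; zero-
variance feature columns are dropped from cross-validation designs (they
carry no information); bootstrap p-values never report 0 (floor 1/N_boot);
grid-search ties prefer stronger regularization; latency ties prefer the
earlier peak.

## Known limitations

Forced alignment itself, electrode localization, brain plotting, and
low-frequency (delta/theta) analyses are out of scope.  The per-electrode
shuffled test departs from the customary unscaled one-sample t (see above).
The TextGrid reader handles long-format interval tiers only.  The
spectrogram front end is a generic filterbank-envelope model, not a
cochleagram.
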