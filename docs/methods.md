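# Methods

This note documents the models, defaults and design choices behind the
package, and what the synthetic-data tests do and do not establish about
real recordings.

## The synthetic study

The generator emulates a two-group oddball study: 10 professional and 10
novice players, 32-channel EEG (extended 10–20 montage, positions from the
standard template shipped with MNE) at 250 Hz, four stimulus blocks:

| block | stimulus (s) | blank (s) | targets | non-targets |
|-------|--------------|-----------|---------|-------------|
| B/RB  | 0.25         | 0.5       | 60      | 240         |
| BT    | 0.4          | 1.0       | 40      | 260         |
| MT    | 0.4          | 1.0       | 40      | 260         |
| ST    | 0.8          | 1.0       | 56      | 168         |

Epochs are 800 ms (200 ms pre-stimulus) for B/RB and 500 ms pre-stimulus
for the game blocks, with the last game-epoch sample falling exactly on
+900 ms (351 samples) so that the tensor stage's −100…+900 ms crop has the
full 251-sample time axis. (The literature mixes inclusive and exclusive
endpoint conventions — 800 ms ↔ 200 samples but 1000 ms ↔ 251 samples; we
keep B/RB at 200 samples and give game epochs the one extra trailing
sample.)

**Target response.** Each target epoch carries three component bumps
(P200 +, N200 −, P300 +) projected onto a posterior spatial pattern
(Gaussian fall-off, scale 55 mm, from the P3/Pz/P4/PO3/PO4 centroid,
normalised to ROI-mean weight 1). A bump is a ±10 ms flat top with Gaussian
shoulders; total effective width 60 ms (P200/N200) or 120 ms (P300). The
flat top spans the measurement stage's ±10 ms peak-smoothing window, so a
noiseless isolated component measures back at exactly its configured
amplitude, and a vanishing (1e−9) quadratic tilt makes the peak sample
unique at the configured latency. Per-subject amplitudes and latencies are
drawn once per subject from the group profile tables (the published
mean ± sd values per paradigm and component); per-trial jitter is Gaussian
with one third of the between-subject sd.

**Background.** Every trial receives 1/f Gaussian noise (exponent 1,
per-channel sd 5 µV — values chosen once as EEG-plausible; the study prints
none) and a posterior alpha oscillation (10 ± 1 Hz drawn per trial, random
phase, amplitude 4 µV before the group scale). The professional profile
carries an alpha-power scale of 1.5 (the study's spectrogram comparison
shows stronger stimulus-locked alpha for that group; no magnitude is
printed — 1.5× is this package's choice).

**Cognitive logs.** Reaction times are shifted lognormal (shift 100 ms)
with the published group means/sds split into between-subject (sd/2) and
within-subject (sd·√3/2) parts; 30 trials per reaction-time test, 23
visual-search trials (consistent with the printed final-score/correct-rate
summaries), correctness Bernoulli at the published rates, and one
counted-targets row per subject for the MT/ST blocks with the published
count-error distributions. A configurable fraction (default 3 %) of RT
trials is replaced by out-of-threshold values to exercise the filtering.

**What the generator does not emulate:** ocular/cardiac artifact
morphologies, channel-specific noise spectra, non-stationary drifts, and
ERP component correlations across paradigms within subject. Passing
recovery tests therefore demonstrates correctness of the analysis chain
under the study's statistical structure, not robustness to every real-world
artifact. One visible consequence: because the planted alpha/ERP pattern is
posterior, the robust-z channel screen can flag the strongest posterior
channels on synthetic data; the 2-channel cap and the fact that IDW
neighbours carry the same pattern keep downstream measures essentially
unchanged.

## Measurement

Component search windows default to P200 150–250 ms, N200 200–320 ms,
P300 280–450 ms, except the ST P300 window (350 ms to stimulus end): under
visual-search load the maximal deflection occurs long after 300 ms. The
windowed-extremum peak replaces the study's manual per-subject inspection
with an automatic rule plus a validity flag (no sample of the correct
polarity ⇒ invalid, never an exception). Near-ties within 1e−6 relative
count as one plateau and resolve to its centre. Fractional-area latency
rectifies (polarity × signal, clipped at 0) within the window, integrates
by trapezoid and locates the 50 % crossing by linear interpolation; it is
scale-invariant and shift-equivariant, and agrees with a 10×-oversampled
oracle within half a sample. Overlapping components bias each other's
measured amplitude (a real property of ERP morphology, most visible for
N200 between two positive neighbours); recovery tests that need exactness
use well-separated latencies.

## Filtering

Filters are linear-phase Kaiser-windowed sinc FIRs (β = 5.65): low-pass
30 Hz order 184 (as published), high-pass 0.5 Hz order 1200 — a 0.5 Hz
cutoff cannot be realised at order 184 (63 % of DC passes); order 1200
leaks ~3·10⁻⁴ of DC and remains applicable to few-second records.
Zero-phase application extends the data by odd reflection (up to 3× the
filter order, never more than the signal length minus one) and convolves
with the kernel centred, cancelling the group delay exactly. Trialized
synthetic data are filtered per epoch; continuous EDF input (read via MNE)
is filtered before epoching.

## VMD and spectrograms

The ADMM uses Wiener-filter mode updates with bandwidth penalty α = 2000,
power-centroid frequency updates, dual ascent τ (default 0 — no exact
reconstruction constraint, noise-tolerant), tolerance 1e−7, ≤500 sweeps.
Centre frequencies are initialised at the K largest well-separated spectral
peaks of the signal; uniform initialisation over a band is available (and
used for the white-noise filter-bank property, where peak seeding has no
meaning). Peak seeding prevents two modes from splitting one narrowband
component between them — with uniform seeding a pure 10 Hz tone and K = 3
ends in a stable 50/50 split across two modes. The signal is mirror-extended
(half left, remainder right; total length always even) and cropped back;
the reflection kink at the epoch boundaries smears ~1/bandwidth samples
inward, which is why spectrograms are cropped to −100…+500 ms before any
statistics, mirroring standard practice for boundary-distorted
time–frequency maps.

Instantaneous frequency is the derivative of the unwrapped analytic phase,
5-sample median-filtered, clipped to the 0–30 Hz grid (101 points, 0.3 Hz
steps) so spectrogram energy equals Σₖ Σₜ aₖ(t)² exactly. Subject-mean
spectrograms get a mild Gaussian smoothing along frequency (σ = 1.5 bins)
before group statistics — the instantaneous-frequency ridge is one bin wide
per trial, and smoothing trades that spurious precision for lower sampling
variance without moving band-scale structure. Subjects, not trials, are the
exchangeable units in all group comparisons; a trial-pooled path is not
provided.

## CPD

Alternating least squares with the spatial factor re-orthonormalised each
sweep by polar projection (SVD of the least-squares target), ridge fallback
for rank-deficient normal equations, tolerance 1e−8 on the fit change,
≤500 sweeps, 5 seeded restarts keeping the best fit (the objective is
non-convex; defaults are reduced where tests need speed). Scale is absorbed
into the trial factor; each component's temporal peak and dominant spatial
weight are made positive (sign flips compensated in the trial factor) and
components are ordered by descending trial-factor energy, resolving CPD's
permutation/sign ambiguity deterministically. Per-subject power is the
*signed* sum of the subject's trial coefficients after this alignment; an
absolute-sum variant is deliberately not the default because the signed sum
is what the alignment makes well-defined. Groups are decomposed jointly
(pooled trials) and split only at scoring, matching the pooled trial-count
bookkeeping of the tensor construction.

## Statistics

Permutation tests are two-sided on Welch's t, exact by enumeration when
C(n, n_a) does not exceed the permutation budget and Monte Carlo with the
add-one rule otherwise; the null-calibration suite checks a type-I error in
[0.03, 0.07] at α = 0.05. Hedges' g uses the exact correction
J(df) = Γ(df/2)/(√(df/2)·Γ((df−1)/2)). TFCE uses E = 0.5, H = 2,
dh = max/100 (standard defaults), one kernel for 1-D lattices, 2-D lattices
and the electrode graph; a point at height exactly h counts as
suprathreshold (both the kernel and its brute-force oracle use a 1e−9
tolerance so integer maps are grid-robust). Inference is max-statistic
(family-wise) over the map with the dh frozen on the observed map. Channel
adjacency connects electrodes within 60 mm on the template montage — at the
spec'd-looking 40 mm most of this montage is isolated (nearest-neighbour
distances run 30–59 mm), so 60 mm is the smallest round radius giving every
channel ≥2 neighbours and a connected graph. Mann–Whitney U delegates to
SciPy with an exact null for untied samples of ≤10 per group (the study's
own tooling); a brute-force enumeration oracle cross-checks it in tests.
Spearman correlations use mid-rank ties; heatmap cells get per-cell
permutation p-values, channel maps get TFCE max-statistic p-values.

The two-criteria rule for small-sample correlation maps is operationalised
as: (1) both members of the close-paradigm pair {MT, ST} show significant
channels whose dominant correlation sign agrees; (2) at least two
significant channels share an adjacency edge. Both thresholds are
configurable; the published rule is qualitative.

## Cognitive metrics

Threshold exclusion first (RTM/RTK 120–500 ms, RTD 140–700 ms), then the
1.5-IQR fence per subject — in that order, which is idempotent. The fence
applies to trial-level time metrics (reaction and search times), not to
per-subject complex parameters (correct rate, final score, count error),
which enter group tests with one value per subject. A summary-statistics
path (mean, sd, n) reproduces printed comparison rows without raw data;
t from summaries and from raw data with matching moments agree exactly.

## Problem sizes

Simulation-based suites run scaled down, chosen once: end-to-end ERP
recovery uses 32 target + 8 non-target trials per subject (study: 56 + 168
for ST), spectral recovery 16 + 4 trials with 300 permutations and 30 TFCE
steps, CPD replicates 16×60×200 rank-2 tensors, null calibration 1000
simulations × 2000 permutations. The one study-sized computation is the
CPD recovery tensor (32 × 251 × 800). Detection-rate thresholds (≥90 % of
20 replicates) follow the recovery-suite design, not post-hoc adjustment.

## Known limitations

- VMD boundary distortion makes full-epoch reconstruction error
  length-dependent; all spectral statistics use the cropped interior.
- The N200 amplitude of the default profiles is partly cancelled by its
  positive neighbours in the synthesised waveform (overlap attenuation),
  so measured group deltas for closely spaced components are smaller than
  the configured deltas, though sign-consistent.
- Printed-summary effect sizes inherit the rounding of the published means;
  g values are reproducible only to ±0.02.
- No ICA-based artifact removal: out of scope; amplitude rejection and
  channel interpolation are the only artifact defences.
- Order-4 CPD on full study-sized spectrogram tensors is supported but
  expensive (minutes); tests exercise it at reduced size.
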