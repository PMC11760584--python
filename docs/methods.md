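# Methods

This note documents the models, conventions and design choices behind
`inkpd`, in the order data flows through the pipeline.

## Input model

A recording is seven equal-length channels sampled by a digitising
tablet: integer x/y coordinates, a timestamp, the button status (0 = pen
in air, 1 = on surface), azimuth [0, 360) and tilt [0, 90] in degrees,
and axial pressure in integer device units below 8192. Files are
SVC-style text, one line per sample; published dialects differ in column
order and in whether the first line carries the sample count, so both
are parameters of `SvcDialect`. Timestamps are converted to seconds via
the dialect's tick duration when known, otherwise by rescaling so the
median step equals the nominal sampling period (1/fs, fs = 200 Hz by
default). Values are written with full float repr so that
read(write(s)) == s holds bit-exactly for every channel.

## Dynamic channels

Displacement is the Euclidean distance between consecutive samples,
with a leading 0 so all channels keep length N. **Velocity is
displacement per unit time** (d_i / Δt_i): for uniform motion
x(t) = v·t this yields a constant velocity v, which is the reading the
derivative chain is built on; acceleration and jerk are successive
finite-difference time-derivatives, each length-preserved by a leading
0. The horizontal/vertical chains use signed Δx and Δy. Derivatives
divide by actual timestamp differences; a zero or negative step (real
tablet logs stutter) is replaced by the nominal sampling period with a
warning, so no derivative can divide by zero.

The moment channel is M_i = P_i·cos(θ_i)·r_i·sin(φ_i) with θ tilt, φ
azimuth (both converted to radians only inside this formula; the Tilt
and Azimuth feature channels keep recorded degrees, since monotone unit
changes cannot alter rank statistics but trigonometry needs radians),
and r_i the distance from sample i to the centroid (x̄, ȳ) of all
sampling points, computed once per recording. Consequences used as test
oracles: M is exactly linear in pressure; M ≡ 0 when tilt ≡ 90° or
azimuth ≡ 0°; translating the trace leaves M unchanged because the
centroid moves with it.

By default all samples (including in-air ones, where pressure is 0)
enter every channel; `ChannelConfig(on_surface_only=True)` restricts to
pen-down samples. `include_moment=False` is the ablation switch
(18 channels, empty moment family).

## TF-ST feature catalogue

373 descriptors per channel, fixed layout (names and count depend only
on configuration, never on signal content). Degenerate inputs map to 0
rather than NaN so feature tables stay rectangular. Group conventions:

* **Basic statistics (14)**: max, min, Q1, Q3, IQR, P1, P99, percentile
  range, median, mean, population SD and variance, mean/median absolute
  deviation.
* **Distribution (15)**: kurtosis and skewness (0 for zero-variance or
  numerically degenerate signals), a 10-bin count histogram spanning
  [min, max], the 20th/80th value percentiles, and the ECDF slope
  0.6 / (P80 − P20) (0 when the gap is 0).
* **Temporal (27)**: lag-1 Pearson autocorrelation (0 if either shifted
  half is constant); peak and valley *values* summarised by mean,
  median, Q1, Q3, P5, P95 (0 each when no extrema exist); counts of
  peaks/valleys, where an extremum is a strict 3-point local
  maximum/minimum (plateaus excluded); peak-to-peak range; signal path
  length Σ√(1 + Δs²); trapezoidal area under |s| over time; Shannon
  entropy (natural log) of the normalised 10-bin histogram; multiscale
  sample entropy (m = 2, tolerance 0.2·SD of the original signal,
  coarse-graining scales 1–3, 0 when no template matches); raw
  sign-change count (zero crossings); local max/min counts; direction
  changes (sign changes of the first difference, zero steps compressed)
  and the same divided by N.
* **Differenced signal (6)**: median, mean, sum of Δs and of |Δs|.
* **Spectral (262)**: FMC_0..FMC_255, the time-mean of a short-time
  power spectrogram (segment min(N, 256), 50 % overlap) interpolated
  onto 256 fixed bins; spectral distance (sum of the gap between the
  cumulative magnitude spectrum and its straight line); fundamental
  frequency (first spectral peak above a 10⁻⁴-of-max noise floor);
  spectral centroid; the frequency of the maximum power bin (DC
  excluded); the 95 %-cumulative-power frequency; the maximum non-DC
  power value.
* **Wavelet & cepstral (49)**: Mexican-hat CWT at integer scales 1–9;
  per scale the absolute mean (WAM), variance, SD and energy
  (mean squared coefficient, so energy = variance + mean², an identity
  the tests verify); one wavelet entropy (Shannon entropy of the
  normalised per-scale energies); 12 MFCCs (frames of min(N, 256)
  samples, 50 % overlap, Hamming window, 40 triangular mel filters up
  to fs/2, log energies with a 10⁻¹² floor, orthonormal DCT-II,
  coefficients averaged over frames). The mel filterbank degrades
  gracefully at low sampling rates (empty filters contribute the log
  floor).

The "common features" baseline set (15 per channel) used in the
feature-catalogue ablation comprises mean, median, max, min, SD, Q1,
Q3, IQR, P1, P99, percentile range, peak count, valley count, direction
changes and relative direction changes.

## Selection and screening

Features are selected per family (kinematic / pressure / angle /
moment) because the families carry different physical meaning and
scale: a random forest (500 trees, fixed seed, impurity importances) is
fitted on training rows only and the top 30 features are kept, ties
broken lexicographically for reproducibility. Selection objects store
the training row index and only ever *project* unseen rows — the test
suite audits this leakage guard. Univariate screening reports, per
feature, a two-sided Mann-Whitney U p-value for two classes (exact
enumeration when both groups have ≤ 10 tie-free observations, normal
approximation with tie correction otherwise) or a Kruskal-Wallis
p-value for three or more, plus |Spearman ρ| against the integer-coded
label (HC = 0, ET = 1, PD = 2; only |ρ| is reported so the coding
affects nothing). Constant features get p = 1, |ρ| = 0.

## eCOA

Bound-constrained minimisation with N coatis over T iterations; all
randomness from one seeded generator. Per iteration:

* **Exploration.** For coati i (1-based), the prey ("iguana") position
  is the global best when i ≥ N/2 and a fresh uniform point in the box
  otherwise — implemented literally as printed, although it inverts the
  original description's tree/ground split; `coa_convention=True` swaps
  the halves, and the ambiguity is deliberately left configurable. An
  escape probability is drawn per coati: with r < 0.5 the soft
  encirclement candidate y = Iguana − r·|2(1−r)·Iguana − x| is tried
  (one r per dimension, reused for both appearances in the formula) and,
  if it does not improve, retried as y + r·LF with componentwise
  Levy-flight steps (Mantegna, β = 1.5, scale 0.01); with r ≥ 0.5 the
  hard encirclement x' = Iguana − r·|Iguana − x| contracts towards the
  prey. Candidates are clipped to the box; acceptance is greedy.
* **Exploitation.** Local bounds lb/t, ub/t shrink with the iteration
  counter; each coati is perturbed by (1 − 2r)·(lb_loc + r·(ub_loc −
  lb_loc)), clipped, greedily accepted.

Greedy acceptance makes the best-so-far trajectory monotone
non-increasing; non-finite objective values count as +∞ and are never
accepted. The plain-COA baseline (`variant="coa"`) removes the escape
branch: exploration always uses the hard encirclement move. Integer
dimensions are handled by rounding masked coordinates before every
objective evaluation and in the reported optimum.

## Classifier and fusion

The boosted classifier is discrete SAMME over weighted CARTs
(exhaustive Gini splitter, midpoint thresholds). Because the tuning
protocol evaluates ~1200 hyperparameter points per family per outer
fold, each costing a 3-fold CV of AdaBoost fits, the tree builder and
boosting loop are numba-compiled; the split choice is verified against
scikit-learn's tree on random weighted problems, and the full booster
is cross-checked against scikit-learn's AdaBoost on held-out data.
Class probabilities are the α-weighted mean of the trees' leaf class
distributions — so a single-estimator ensemble returns exactly that
tree's probabilities — and the predicted class is the argmax. A round
with zero weighted error keeps that tree (α = 1) and stops; a round at
or worse than chance stops boosting (kept with negligible weight if it
is the first). `min_samples_split` is a *fraction* of the training set,
as its [e⁻⁴, 1] search range implies.

Hyperparameters are tuned by eCOA (population 50, 10 iterations, the
same budget the tuning protocol fixes) minimising 1 − stratified 3-fold
inner-CV accuracy computed on the outer-training rows only; tuning is
re-run per outer fold and per family, the leakage-safe reading of the
protocol. Family probabilities are fused by Eq-style adaptive weights
w_i^k = n_i^c / N_k (n_i^c = number of families whose argmax agrees
with family k's, N_k = number of families), used unnormalised by
default — normalising rescales the fused vector without moving the
argmax, which is unit-tested. Metrics: accuracy; sensitivity and
specificity from one-vs-rest confusion counts, macro-averaged for three
classes (for two classes the positive class is the lexicographically
last label, PD for HC/PD); AUC from normalised fused scores, one-vs-one
macro for multiclass. The outer harness is stratified 5-fold CV with
predictions pooled across folds before computing the report.

## Synthetic cohorts

The generator emulates the acquisition setting the pipeline targets:
an Archimedean spiral (or stroke sweep) traced at 200 Hz with a speed
profile built from lognormal velocity pulses (two per revolution — the
standard kinematic model of rapid strokes), quantised to integer tablet
units and 8192 pressure levels. Class pathology:

| class | tremor band | amplitude (units) | micrographia | pressure SD | angle drift SD |
|-------|-------------|-------------------|--------------|-------------|----------------|
| HC | 8–12 Hz | 25 | — | 150 | 1°/√s |
| PD | 4–6 Hz | 300 | 8 %/rev | 400 | 3°/√s |
| ET | 5–8 Hz | 500 | — | 250 | 2°/√s |

Amplitudes are in tablet units (~200 units/mm on a Wacom-class tablet,
so PD ≈ 1.5 mm, ET ≈ 2.5 mm — the magnitudes tremor studies report);
HC's small high-frequency component models physiological tremor; the
baseline pressure is 3000 with a slow sinusoidal wander. The tremor
displacement is split evenly between the path-orthogonal direction
(kinetic tremor follows stroke geometry) and a fixed per-subject hand
axis; the fixed component puts a clean spectral line at the tremor
frequency, whereas a purely path-orthogonal oscillation on a rotating
trajectory appears *only* as modulation sidebands at f ± the rotation
rate and would make the injected frequency unrecoverable in principle.
Ground truth (each subject's drawn tremor frequency and amplitude) is
logged in a separate table the pipeline never reads. Child seeds are
spawned deterministically from the root seed, so a cohort is
reproducible byte for byte.

`estimate_tremor_frequency` recovers the injected frequency from the
planar velocity (summed power spectra of the horizontal and vertical
velocity components), restricted to the 3–15 Hz physiological tremor
band — as tremor analyses conventionally do, and necessarily here
because the stroke rate and its harmonics dominate below 3 Hz. A 3-bin
integration absorbs leakage when the line falls between DFT bins, a
3-bin power centroid refines below bin width, and when the task's
rotation rate is supplied, line-vs-sideband ambiguity is resolved by
sideband symmetry (the true line has sidebands on both sides).
Validated accuracy: worst error 0.06 Hz over 600 PD/ET subjects across
ten cohort seeds.

What the generator does **not** model: stroke-level letter shapes,
pen lifts within the spiral task, bradykinesia-related hesitations,
session effects, device jitter beyond quantisation, or inter-subject
variability in tremor amplitude within a class. Passing the end-to-end
tests therefore shows the pipeline recovers the class structure it
encodes (distinct tremor bands/amplitudes, micrographia, pressure
variability) — not clinical performance on real patients.

## Study conditions and problem sizes

The bundled end-to-end study uses 30 subjects per class (HC/ET/PD),
8-second spiral recordings, the full 7087-feature catalogue, top-30
selection per family, tuning at population 50 over 10 iterations with
3-fold inner CV, and stratified 5-fold outer CV — sizes chosen once as
a desk-scale study a single workstation reproduces in minutes. The
null-cohort control re-runs the identical pipeline on a cohort whose
classes share one parameter set; its accuracy is expected inside the
binomial 95 % band around 1/3. The moment ablation re-runs the pipeline
on the same feature table with the moment family removed.

## Numerical choices and limitations

* Ties in top-k selection and tree splits break deterministically
  (lexicographic names; midpoint thresholds between distinct values).
* Boosting weight updates clip the exponent at 500 and renormalise each
  round; zero-weight leaves (possible after extreme learning-rate
  updates) predict the uniform distribution.
* The optimizer treats NaN/Inf objectives as +∞ rather than erroring,
  so a pathological hyperparameter point cannot kill a tuning run.
* The exact reference semantics of a handful of catalogue names
  (autocorrelation lag, "spectral distance", the traveled-distance
  formula) follow the conventions recorded above; alternative readings
  exist and would change feature values but not the pipeline contract.
* Known limitation: with strongly separable synthetic classes the tuned
  accuracy saturates at 100 %, so the end-to-end tests bound behaviour
  from below (≥ 0.85 macro accuracy) and the null cohort bounds it
  around chance; they cannot discriminate between good and excellent
  hyperparameter tuning. The optimizer benchmarks on sphere/Rastrigin
  cover that axis separately.
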