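# Methods

## Signal model and flow estimation

First-pass perfusion CMR tracks the transit of a gadolinium bolus
through the left ventricle (LV). Under linear, stationary tracer
kinetics the myocardial enhancement curve is the convolution of the
arterial input function (AIF) with a tissue impulse response whose
initial height equals tissue blood flow. The deconvolution is
ill-posed, so the impulse response is constrained to the Fermi family

    h(t) = F / (1 + exp(k (t − τ₀))),     t ≥ 0,

a monotonically non-increasing plateau-then-decay shape with three
parameters: flow amplitude `F`, decay rate `k` (1/s) and shoulder width
`τ₀` (s). A fourth parameter, the arrival delay `t_d` (s), shifts the
AIF. Myocardial blood flow is read out as `MBF = h(0) =
F / (1 + exp(−k τ₀))`. The discrete forward model is

    C_t[i] = Δt · Σ_{j≤i} C_a(t_j − t_d) · h((i−j) Δt),

with the delayed AIF evaluated by linear interpolation so the model is
smooth in `t_d`. Flow units are arbitrary-but-consistent: no absolute
mL/g/min calibration is attempted, because the clinical decision
quantity — the myocardial perfusion reserve MPR = MBF_stress/MBF_rest —
is invariant to any common scaling of signal and AIF. Ischemia is
defined per segment as MPR < 1.5, with strict inequality (MPR exactly
1.5 is negative).

### Fitting

`FermiDeconvolution.fit()` runs bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) with bounds
F ∈ [0, ∞), k ∈ [0, 5] s⁻¹, τ₀ ∈ [0, 30] s, t_d ∈ [0, 10] s, from three
starts: `F` initialized from the ratio of the tissue peak to the peak
of the cumulative AIF integral (the constant-impulse-response limit),
and k ∈ {0.05, 0.2, 0.5}. The best residual wins; ties break toward
smaller k, and the remaining starts are skipped once a start reaches an
essentially exact fit (RMS < 1e−9 × curve scale). Residuals are
evaluated from the AIF arrival frame to the end of the series by
default (a first-pass-only window is available via `fit_window`).
Parameter uncertainties come from the Gauss–Newton covariance
σ²(JᵀJ)⁻¹. Degenerate input — an identically zero tissue curve —
short-circuits to MBF = 0 without invoking the optimizer.

The per-segment statistic over pixel flows is the **median** of
converged pixels (robust against isolated fit failures); the mean is
available by configuration. MPR is formed from the segment statistics
("ratio of medians"), not pixel-wise; segments with non-positive rest
flow are marked indeterminate and excluded from calls with a warning.
Territory and patient positivity use an any-segment rule
(`min_ischemic_segments = 1`) over the fixed 16-segment map
LAD = {1,2,7,8,13,14}, RCA = {3,4,9,10,15}, LCX = {5,6,11,12,16}.

## Dual-bolus AIF

The AIF is measured on a 1:10 diluted pre-bolus (the protocol injects
0.0075 then 0.075 mmol/kg, so the dose ratio — and default dilution
factor — is 10) to avoid signal saturation in the blood pool. The
curve is the mean blood-pool signal per frame minus the mean of the
first 5 (pre-contrast) frames, times the dilution factor. Bolus
arrival is the first frame exceeding baseline + 3σ of the pooled
curve. The quality score is the peak enhancement divided by the
pixel-level pre-contrast noise SD — i.e. the contrast-to-noise ratio of
the diluted bolus. The pixel-level (rather than pooled-curve)
denominator is deliberate: a pooled 5-sample SD is numerically
unstable, and the pixel-level form makes the gate behave as intended —
a pre-bolus whose noise reaches half its peak scores ≈ 2, well below
the default threshold of 5. A failed gate stops the pipeline with
status `quantification-failed` and no flow output, reproducing the
failure mode seen in practice when the diluted pre-bolus is too weak to
measure.

## Motion correction

Respiratory motion is corrected in-plane, per slice. The region of
interest is the 5-px-padded bounding box of the largest connected
component of pixels whose temporal SD reaches the slice's 95th SD
percentile — the region the bolus actually transits. Each frame is
registered to its predecessor by derivative-free (Powell) maximization
of the Pearson correlation within the ROI over a full 6-parameter
affine transform anchored at the ROI centre; a translation-only stage
seeds the full search, which is capped at 500 cost evaluations per
frame. Pairwise transforms are composed so every frame maps into
first-frame space; resampling is bilinear with edge-value padding.

Two numerical choices matter here:

* The correlation cost is evaluated on images smoothed with a 1-px
  Gaussian (the output is resampled from raw data). Without this, the
  sub-pixel blur introduced by bilinear interpolation can itself raise
  the correlation of already-aligned frames, and re-registration of a
  corrected series would drift.
* A pair transform is accepted only if it improves the correlation by
  at least 2e−3 over the identity; otherwise the identity is kept.
  The gate sits between the measured ceiling of spurious gains on
  aligned frames (~1e−3, caused by genuine but physically meaningless
  distortions when frame contrast is changing) and the gains from real
  sub-pixel misalignment (≳1e−2). This keeps motion-free series
  bit-identical and makes the procedure idempotent, at the cost of
  ignoring motions small enough to produce sub-2e−3 gains (below
  ~0.1 px on the phantom).

On noiseless phantoms with known sinusoidal translations up to 5 px the
recovered translations are accurate to ~0.05 px mean absolute error.

## Contours and segment map

The temporal maximum-intensity projection (MIP) of the corrected series
gives a high-contrast feature image. The LV centre is the centroid of
the brightest connected component above the Otsu threshold; blood-pool
intensity is sampled in a 3-px disc around it. 360 rays are cast from
the centre: per ray the endocardial edge is the first drop below 60% of
blood-pool intensity, and the epicardial edge the subsequent drop below
40% of the myocardial ring's median intensity (the ring intensity is
estimated 0.5–2.5 px beyond the endocardial edge). Profiles with up to
25% missing rays are filled by periodic interpolation; more is a
delineation failure, at which point manual contours may be supplied
(`override_contours`, provenance recorded). Both radius profiles are
smoothed by a 15° periodic moving average. The 60%/40% fractions and
the smoothing window are package choices, exposed as keyword arguments;
they are robust on the phantom (sub-pixel mean radial error) but real
data may need tuning and manual optimization, which is why the
pipeline's operator intervention point is exactly here.

Segments are assigned by angle from the LV centre, counter-clockwise
from a reference angle at the anterior RV insertion (default 90°,
user-configurable for real data): 6 equal sectors on the basal and mid
slices (labels 1–6, 7–12), 4 on the apical slice (13–16). The
16-segment scheme is the standard 17-segment AHA model without the
apical cap, which 3 short-axis slices do not cover. By default the
stress-series contours define the analysis frame for both stress and
rest (one geometric frame is required to form segment-level MPR);
independent rest delineation is available by configuration.

## Phantom generator

The generator emulates the acquisition the pipeline targets: 3
short-axis slices, 120 dynamics per slice at 0.5 s spacing, 1.9 mm
pixels on a 72² matrix, an annular myocardium (endo/epi radii 8/14 px
≈ 15/27 mm), a central blood pool, and a pre-bolus series at 1/10 of
the main bolus. The AIF is a normalized gamma-variate (amplitude 4
signal units, onset 8 s, α = 3, β = 2 s — a realistic ~6 s bolus width)
with a 15% recirculation pass delayed 25 s; the closed-form peak
(amplitude, at onset + αβ) anchors the delineation and AIF tests.
Myocardial pixel curves follow the Fermi forward model with per-segment
parameters; defaults are rest MBF = 1/60 and stress MBF = 3/60 flow
units (k = 0.25 s⁻¹, τ₀ = 4 s, t_d = 1.5 s), i.e. a healthy reserve of
3 with myocardial enhancement a realistic fraction of blood-pool
enhancement. `PhantomConfig.with_segment_mpr` prescribes arbitrary
per-segment reserves for defect studies.

Edges are rendered with 1-px linear partial-volume transitions
(realistic, and required for stable sub-pixel registration); pixels
inside the transition bands mix compartments, so ground truth exposes
both the full ring mask and a pure-myocardium mask on which pixel
curves equal their segment curve exactly. Motion is a smooth
two-frequency sinusoidal translation (respiratory-like, period 5 s,
default amplitude 2 px), applied by bilinear shifting and recorded
per frame. Noise is additive i.i.d. Gaussian (default SD 0.05 signal
units ≈ 1/26 of the stress tissue peak); a separate
`prebolus_noise_sd` can degrade the pre-bolus alone to reproduce the
AIF quality-failure mode. An optional dark-rim artifact multiplies the
innermost subendocardial ring by 0.6 for the 5 frames around the bolus
peak. Identical seeds give bit-identical output.

What the phantom does **not** emulate: k-t undersampling artifacts,
through-plane motion, T1-saturation nonlinearity of the signal,
Rician noise statistics, and anatomical background structures. Passing
tests therefore demonstrate correctness of the algorithms under the
stated model, not clinical performance on scanner data.

## Statistics layer

`confusion`/`accuracy_stats` do exact integer arithmetic; percentages
are rounded half-away-from-zero to one decimal (the usual clinical
reporting style) and intervals are exact Clopper–Pearson. The McNemar
test is the exact binomial form (2·P(X ≤ min(b,c)) at p = ½, capped at
1; p = 1 for no discordant pairs) — appropriate at the small discordant
counts of a ~50-patient cohort — with the chi-square approximation as
an option. Group comparisons use classical one-way ANOVA plus pairwise
t-tests with Bonferroni multiplication (capped at 1); proportions use
Pearson chi-square without continuity correction or two-sided Fisher
(zero-margin tables are Fisher-only).

`reference_study_report` recomputes the printed accuracy figures of the
validation cohort the pipeline was developed against: 53 patients, 16
CAD-positive (prevalence 30.2%), quantification successful in 51 with
the 2 failures occurring in CAD-negative patients. The quantitative
confusion matrix is reconstructed from the printed sensitivity (68.8%)
and specificity (94.3%) on the analysable cases by nearest-integer
rounding (TP = 11/16, TN = 33/35 — the unique integers consistent with
all the printed percentages), giving agreement 44/51 = 86.3%. Counting
the 2 failed cases as missed diagnoses yields the failure-penalized
concordance 44/53 = 83.0% and specificity 33/37 = 89.2%. Vessel-count
shares (8/5/3 of 16) and per-artery lesion prevalences (9/8/13 of 53)
are recomputed the same way. The cohort's per-reader-level accuracies
(83.6/65.7/55.7% for levels 3/2/1) carry ± SDs across 3 operators and
cannot be recomputed without reader-level data; the package instead
simulates reader calls at the published per-level sensitivity and
specificity and reproduces the level-3 > level-2 > level-1 ordering.

## Problem sizes and determinism

Tests and the acceptance script run phantoms at the protocol frame
count (120 dynamics) for deconvolution studies and at 40–60 dynamics
for registration and end-to-end studies, with the full 72² matrix for
geometry-sensitive checks and 56² for pipeline smoke tests; these sizes
keep the suite at a few minutes on one CPU while leaving every
algorithmic path identical. All stochastic components (noise, reader
simulations) draw from `numpy.random.default_rng` seeded explicitly;
two runs with the same configuration and seed produce byte-identical
CSV/JSON outputs.

## Known limitations

* Correlation-based affine registration cannot distinguish a small
  geometric distortion from a genuine alignment gain when frame
  contrast changes rapidly; the acceptance gate above bounds, but does
  not eliminate, this effect.
* The polar delineation assumes a star-shaped myocardium around a
  bright compact blood pool; papillary muscles, extreme defects at the
  blood-myocardium interface, or severely off-centre hearts will need
  the manual override path.
* The Fermi model assumes a single well-mixed tissue compartment;
  quantities other than MBF = h(0) (e.g. volume of distribution) are
  not identified, and absolute flows require a calibration the package
  does not perform.
* MPR-based calling inherits rest-flow noise: at low rest SNR the
  ratio's error is dominated by the denominator, which is why the
  segment median and the converged-pixel filter matter.
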