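# Methods

`perfstab` quantifies how reproducible CT-perfusion (CTP) stroke metrics are
from one scan to the next. Because repeated patient CTP is rare and no public
paired data exist, the package ships a synthetic dynamic-CTP phantom with
exact hemodynamic ground truth; every stage of the analysis pipeline is
validated against it. This note documents the models, the parameter choices
and their rationale, the numerical details, and the limitations of what the
phantom can and cannot show.

## 1. Forward model (synthetic phantom)

**Anatomy.** A two-hemisphere ellipsoidal "brain" (default ~1.1 L) with a
grey-matter shell (~60 % of brain volume) around a white-matter core, on a
64×64×24 grid at 3×3×4 mm (inside the protocol ranges of 1.5–3.5 s temporal
sampling and 38–55 s duration; default dt 2 s, duration 50 s). Two
2×2×3-voxel vessel clusters straddle the midline: an artery carrying the
undelayed bolus and a vein carrying it 4 s later at 1.3× amplitude (veins
enhance more strongly than arteries in CTP). An atlas partitions each
hemisphere into 10 mirror-symmetric regions named after the ASPECTS scheme
(C, L, IC, I, M1–M6).

**Hemodynamics.** Tissue curves follow the indicator-dilution relation

    c(t) = b + k · CBF · (AIF ⊛ R)(t − δ),    R(t) = e^(−t/MTT),

with baseline attenuation `b`, bolus delay `δ`, an optional exponential
dispersion kernel, and the unit constant `k = 1/6000` mapping CBF in
mL/100 g/min to 1/s at unit tissue density. The arterial input is a gamma
variate `A·(t−t₀)^α·e^(−(t−t₀)/β)` (defaults A = 165, t₀ = 10 s, α = 2,
β = 1.5 s; peak ≈ 200 HU). Convolutions are evaluated on a 0.1 s internal
grid and sampled at the scan times, so the discrete analysis never sees its
own discretization. Noise is i.i.d. Gaussian in HU (default sd 2 HU for CTP
samples, 1.5 HU for NCCT) — an approximation of post-reconstruction CT noise
without streaks, beam hardening or motion.

**Tissue constants** (phantom constants, not literature claims): GM
CBF 60 / MTT 4 s / 35 HU; WM CBF 25 / MTT 5 s / 28 HU.

**Lesion.** An ellipsoidal penumbra (default ≈40 mL) with a nested core
(≈15 mL). The penumbra keeps 85 % of normal CBF; the core 15 %. The bolus
delay grades from 8 s at the penumbra rim to 11 s at its centre
(hypoperfusion severity grades from rim to core in vivo; the gradient also
gives the Tmax-derived metrics a non-degenerate scan-to-scan distribution).
The penumbra fraction of 0.85 is deliberately high so that white-matter
penumbra stays above the 30 % relative-CBF core threshold under global,
GM-dominated normalization — the well-known GM/WM confound of global rCBF
thresholds, which the phantom makes explicit rather than hides.

**Ground truth** masks are derived from the true maps with the same
thresholds the analysis uses (Tmax > 6 s; rCBF < 30 % of the normal-tissue
median, normal = Tmax < 4 s), so truth and pipeline output are directly
comparable. True Tmax is the delay plus the peak offset of the (possibly
dispersed) residue, computed numerically — not assumed equal to the delay.

**Scan pairs and scenarios.** A pair is one simulated patient scanned twice
(interval drawn from 0.7–8.8 h; acquisition clock times are written as
`HHMMSS.ffffff` strings and the interval is recomputed from them, with a
+24 h midnight wrap). Scenarios: `stable` (identical truth, fresh noise),
`new_occlusion` (second 20 mL lesion), `thrombus_migration` (lesion moved
24 mm), `bolus_truncation` (bolus onset +20 s on a 38 s protocol, so the AIF
is still above 20 % of peak at the last sample), `coverage_shift` (z-coverage
moved 4 slices), `high_noise` (noise ×3). Cohorts draw each scan's dt and
duration independently from the protocol ranges ("protocol jitter"),
mirroring the scanner heterogeneity of real repeated imaging.

## 2. Perfusion quantification engine

**Denoising.** Spatial Gaussian of 4 mm FWHM per frame plus a temporal
Gaussian of sd 1.5 frames. Both were chosen by phantom experiments trading
two failure modes: spatial kernels erode small lesions at tissue boundaries,
while insufficient denoising lets the max-over-time statistics (CBF, Tmax)
inflate in low-SNR white matter, seeding spurious hypoperfusion clusters.
Temporal smoothing attenuates the latter without spatial erosion. Rigid
frame-to-first motion correction (SimpleITK) is available but off by default
— the phantom has no motion.

**Bolus arrival** is the first frame whose whole-brain mean enhancement
exceeds a robust (median/MAD) pre-bolus level by 3 MAD-sd, with a 0.3 HU
floor so the rule is defined for noise-free input. The baseline volume is
the mean of the pre-arrival frames (first three, with a warning, if fewer
than three are clean).

**AIF selection.** Candidates are the top 0.5 % of brain voxels by peak
enhancement, subject to a 60 HU amplitude floor (vessels exceed 100 HU at
CTP tube voltages; tissue and partial-volume halo voxels stay far below —
the floor is what keeps halo voxels from corrupting the clustering) and a
spatial-contiguity filter (components ≥ 4 voxels). Two-group k-means on
standardized (time-to-peak, peak amplitude) separates arterial from venous
pools; the earlier-peaking group is arterial. Within it, curves are ranked
by `peak / (FWHM · TTP)` — tall, narrow, early — and the AIF is the average
of the top 5, with ties broken by lowest linear voxel index (fully
deterministic).

**Deconvolution.** The convolution matrix is built from Simpson-weighted AIF
samples `(a_{j−1} + 4a_j + a_{j+1})/6` scaled by dt — the rectangle rule
underestimates sharp residue peaks by 20–40 % at clinical sampling — as a
zero-padded block-circulant matrix (delay-insensitive; plain Toeplitz
available). With `A = U S Vᵀ`, the residue estimate is the Tikhonov-filtered
back-substitution with filter factors `σ²/(σ² + (λσ₁)²)`, `λ = 0.15` by
default; the SVD is computed once per scan and applied to all voxels. The
regularized-SVD formulation is used even though the software this models
describes its penalty as L1: an L1 penalty admits no SVD filter-factor form,
so the two descriptions cannot both hold; the SVD form is the one with a
defined algorithm.

**Maps.** CBF = max of the residue estimate (deconvolution units, 1/s; no
absolute calibration constants, since every reported metric is relative or
in seconds); Tmax = time of that maximum, first maximum on ties;
CBV = trapezoidal area of the enhancement curve over the AIF area, negatives
clipped; MTT = CBV/CBF where CBF is positive, NaN elsewhere. rCBF and rCBV
are percentages of the median over normally perfused tissue (Tmax < 4 s);
an empty reference set is an error, never a silent fallback. Negative
residue values are not clipped in k(t) itself, only map-level negatives.

**Known systematics.** At λ = 0.15 the filtered maximum underestimates
absolute CBF by roughly 25–45 % depending on MTT/dt; Tmax carries a uniform
+1-sample offset from the smeared causal edge of the residue. Both cancel in
the relative and threshold-based quantities the package actually reports.
The quantitative-accuracy study (below) therefore runs at an operating point
matched to its noise level.

## 3. Lesion volumetry

Brain mask: 10–60 HU window, largest connected component, holes filled.
Hypoperfusion = brain ∧ Tmax > 6 s; core = hypoperfused ∧ rCBF < 30 %
(strict inequalities, matching the printed thresholds; the core is
restricted to the hypoperfused region as mismatch software does —
configurable). Two cleanup passes follow: an in-plane 3×3 majority vote
(in-plane only, because 4 mm slices are thick relative to 3 mm in-plane
resolution; a 3×3×3 vote erodes thin lesions) and removal of clusters below
1 mL. Volumes are voxel counts × voxel volume.

## 4. Automated ASPECTS

Atlas labels are overlaid in identity mode (the phantom supplies exact
labels) or after a moment-based affine alignment to a template — a
deliberate simplification of non-rigid template registration, which adds no
test power on rigid synthetic heads. Each region is summarized by its median
HU (trimmed mean available); a region is abnormal when the contralateral
homolog's summary exceeds its own by more than 2.25 HU (strict), each
hemisphere scores 10 − flags, and the affected side is the one with more
flags ("none" on ties). The median was chosen over a full-histogram distance
for robustness; whether CSF should be excluded from region histograms is
moot on a CSF-free phantom.

## 5. Repeatability metrics and agreement statistics

Per scan: core and hypoperfusion volume (mL), ASPECTS, median Tmax inside
the hypoperfusion volume (s, native units), and median CBF / NCCT HU inside
the core as a percentage of the mirrored contralateral region (mirroring is
a flip across the midsagittal grid plane; an affine that is not axis-aligned
raises rather than guessing the midline). Metrics over empty regions are NaN
("undefined"), never zero, and are dropped pairwise with per-metric n.

Per cohort: differences are scan2 − scan1 throughout. Bland–Altman bias,
sample SD (n−1) and 95 % limits of agreement (bias ± 1.96 SD); Pearson r
between scans; two-sided paired t-test; and the interval association,
operationalized as the Pearson correlation of signed differences with the
inter-scan interval (rank correlation available by config; for a simple
linear fit the slope test gives the same p). α = 0.05, two-sided, no
multiplicity correction. Pairs with disruptive scenarios (new occlusion,
thrombus migration) are excluded from the statistics and listed in the
report. Zero-variance correlates yield NaN statistics; identical scans give
a paired-t p of 1 by convention.

## 6. Validation studies and their operating points

* **Deconvolution oracle** — the SVD filter path must match the direct
  normal-equations solve to 1e−8 on ≤20-point systems, and an impulse AIF
  (rectangle quadrature, λ=0) must return the tissue curve exactly.
* **Parameter recovery** — a 5×5×3 grid of true (CBF, MTT, delay) states in
  uniform 6×6×4-voxel blocks at 1 HU noise, read out as interior-block
  medians, with the true AIF supplied; spatial smoothing 6 mm, temporal
  smoothing off, λ = 0.05. The study isolates the deconvolution, so its
  regularization is matched to the effective post-smoothing noise (the
  discrepancy-principle logic) and the temporal denoiser — whose purpose is
  threshold-map stability, irrelevant on a block phantom — is excluded.
  Passing bars: median |Tmax error| ≤ one time sample, median relative CBF
  error ≤ 15 %.
* **Lesion recovery** — spherical lesions sized so the true hypoperfusion
  volume is 10/30/60 mL, full default pipeline at default noise, three noise
  seeds each: volumes within ±10 % and Dice ≥ 0.90 (medians over seeds);
  core ⊆ hypoperfusion always.
* **ASPECTS calibration** — constructed hypodensities of 5 HU in k regions
  score exactly 10−k noise-free; a 2.25 HU difference is not flagged; the
  false-flag rate on 100 lesion-free NCCTs at 1.5 HU noise is ≤ 5 % per
  region-side.
* **Stable cohort** — 200 independent stable pairs with protocol jitter,
  full pipeline. Zero must lie inside the 95 % limits of agreement of every
  metric, and the paired-t and interval-association tests must reject at
  their nominal 5 % (±3 points) over 2000 subsampled cohorts of 20 pairs.
  Cohort size 20 balances t-test normality (size 10 under-rejects, ~1 %, on
  the heavy-tailed volume differences protocol variation creates) against
  subsample dependence on the 200-pair pool. Rates are evaluated for the
  four metrics whose differences are continuous; ASPECTS and median-Tmax
  differences are exactly quantized on the phantom (region flags are
  deterministic at 5 HU vs the 2.25 threshold; Tmax lives on the sampling
  grid), so a t-test rejection rate is degenerate for them and the study
  asserts unbiasedness and LoA containment instead.
* **Disruptive-event sensitivity** — 50 new-occlusion pairs (+20 mL true
  growth, same protocol both scans): growth is "detected" when the measured
  hypoperfusion increase exceeds half the simulated growth; the detection
  rate must be ≥ 95 % and every such pair must appear in the report's
  exclusion list.

`scripts/acceptance.py --seed N --out results/acceptance.json` re-runs all
of these from scratch (cohort size 120 by default for runtime) and writes
the numbers as JSON.

## 7. What the phantom does and does not show

Passing these studies shows the pipeline is internally consistent, unbiased
across repeats, and sensitive to genuine change under the stated noise and
geometry. It does not establish accuracy on real heads: the phantom has no
skull, CSF, motion, contrast recirculation, beam hardening or anatomical
variability; its residue function is mono-exponential by construction (real
tissue residues are unknown; the software this models does not state its
assumed family); and its noise is white. Known quantitative limitations,
visible in the validation numbers rather than hidden: absolute CBF carries
the regularization damping discussed above, and infarct-core volumes at
default noise are biased low by roughly a third (partial-volume mixing at
the sharp core boundary pushes voxels above the 30 % rCBF cut, and the
max-over-time statistic inflates near-zero-flow voxels) — core-dependent
*relative* metrics remain well behaved, which is exactly the
lower-variability-of-intensity-metrics behaviour repeated clinical CTP
shows. Threshold-derived volumes are the noisiest metrics here as well;
the repeatability study reproduces that hierarchy rather than assuming it.
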