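# Methods

`mvgc` implements a drone-based phenotyping workflow for seedling-stage
winter wheat.  This note documents the models, the numerical choices, the
synthetic-data generator, and the limits of what desk-scale tests can show.

## The multiview ground-cover image

A survey flight captures each plot in dozens of overlapping oblique views.
After per-view plant/soil segmentation, every view is resampled into a
common plot coordinate frame and the binary masks are averaged pixel-wise:

    mvImg(x, y) = (1 / n_Img) Σ_i segImg_i(x, y).

Pixel values are therefore *fractions of views* classifying that spot as
plant.  Dense canopy or ground-hugging leaves score near 1; erect or sparse
plant parts, whose apparent position shifts with the viewing angle, score
intermediate fractions.  That viewing-geometry signature — not resolvable
from any single view — carries the information all downstream traits use.

Key conventions:

* Plot frames are oversampled threefold relative to the nominal ground
  sampling distance (GSD), so nearest-neighbour resampling of binary masks
  loses at most one sub-pixel per edge; the effective GSD is nominal/3.
* Plots are shrunk by a buffer `B = tan(AOV/2)·h_canopy + E_ref` before
  sampling so that neighbouring plots seen obliquely cannot leak in.  With
  the default 0.25 m buffer, a 40° angle of view and 0.1 m georeferencing
  precision, canopies up to 0.41 m can be monitored.
* Views in which a plot is not fully visible are excluded by default: the
  aggregate divides by a single view count and partially visible plots
  would bias the mean.  A per-pixel-denominator mode is available.
* Aggregation accumulates in 64-bit integers, so sums are exact.

## Thermal time

Phenology is tracked in growing degree days accumulated from hourly air
temperature, `Σ_d Σ_h max(T_h − T_base, 0)/24` with `T_base = 0 °C` for
winter wheat.  Days with fewer than 24 hourly records are rejected rather
than rescaled — the divisor 24 is part of the definition.  Each plot carries
a thermal anchor `GDD_GS30` (beginning of stem elongation, BBCH 30) so that
genotypes of different earliness can be compared on the relative axis
`ΔGDD_GS30 = GDD − GDD_GS30`.

## Pixel segmentation

At 3 mm GSD, seedling leaves are narrower than a pixel and the camera's
Bayer mosaic means only half the sensor sites measured green directly.  The
classifier therefore works at green Bayer positions only; red and blue are
interpolated there from the two adjacent same-channel sites (edge-padded at
borders).  Each position carries 17 predictors: R, G, B; XYZ; nonlinear
sRGB (gamma-encoded, D65); HSV; CIE L\*a\*b\* (D65); and the indices
ExG = 2g − r − b and ExR = 1.4r − g on sum-normalised chromatic
coordinates.  A random forest (55 trees, min split 4, min leaf 6, max
features 6, max depth 95, seed 17) votes plant vs. soil; the missing
red/blue positions are filled from the 3×3 neighbourhood maximum of green
predictions and one binary 3×3 opening removes speckle.  Already-demosaiced
imagery is handled by declaring a virtual mosaic, preserving the
green-position subsampling semantics.

## Trait extraction

**GS30 index.** Ten ground-cover percentiles `mvGC_i` (fraction of pixels
strictly above i/100, i = 10…100; the strict inequality makes `mvGC_100`
identically zero, kept as a faithful endpoint) feed an RBF support-vector
regressor (cost 32, gamma 0.125) trained on pairs filtered to
±20 ΔGDD_GS30 — the band where the pseudostem-erection signal is
informative.  Predictions are clamped to the training response range (no
extrapolation).  Per plot, a line `index = a·GDD + b` is intersected with
zero, GS30 = −b/a.  Two guards stabilise the line: campaigns whose index
sits on a saturation plateau (change below 2% of the plot's index range
against both neighbours — a rule invariant to the index amplitude) are
excluded, and the fit is localised to ±2 windows around the
campaign nearest the zero crossing.  Both address the same failure mode —
the regressor saturates outside its training band, and saturated campaigns
carry no timing information.

**Plant count.** Local maxima of the multiview image (fraction > `i_peak`,
separation ≥ `d_min`; a connected plateau counts once, ties broken by scan
order) seed a watershed on the inverted fraction landscape restricted to
pixels above `i_thresh`.  Region areas map to counts through a calibrated
linear relation, `N̂ = Σ_j (a_W·A_j + b_W)`, with the intercept applied per
region as the relation is written; an intercept-once variant is kept as a
diagnostic.  Defaults `i_thresh = 0.10`, `i_peak = 0.30`,
`d_min = 25 mm / effective GSD`; calibration against reference positions is
mandatory before prediction, and is best done in the window 5–15 days
before GS30, before canopies merge into unresolvable mats.  The
intermediate-level trait is the median of the corrected time-point counts.

**Shoot count.** Apparent leaf area `LA = Σ_j mvImg_j²` (squaring
compensates the off-nadir-skewed zenith distribution of survey flights; the
exponent is configurable) relates to shoot number through a logistic in
`log1p(N_S)` whose asymptote is fixed at the LA of 90% cover and whose
midpoint and scale drift linearly with ΔGDD_GS30:

    LA = Asym / (1 + exp((xmid(Δ) − log1p(N_S)) / scal(Δ))).

Fitting groups triplets into ΔGDD bins of half-width 12.5 GDD, fits
(xmid, scal) per group with `Asym` fixed and bounded parameters
(scal ∈ [10⁻³, 20]), drops groups whose shoot counts span less than 0.05 in
log1p (scal unidentifiable there), and regresses the group parameters on
the bin centres.  The closed-form inverse
`N̂_S = expm1(xmid − scal·ln(Asym/LA − 1))` converts leaf areas to shoot
counts (LA ≥ Asym clamps to 0.999·Asym with a warning; the exponent is
clipped at ±700 to stay finite).  Per plot, the inverse-exponential
tillering model `N_S,t = N_S − exp(−a·ΔGDD)` is fitted over
−200 ≤ ΔGDD < 0 (outside this window the model extrapolates); with fewer
than three points the final shoot count falls back to the series median and
the rate is reported missing.  Early negative model values are allowed
during fitting and clamped only for reporting.

Nonlinear fits use bounded least squares from five data-driven starts
(fixed seed, tolerances 10⁻¹⁰); error metrics follow the
reference-minus-estimate sign convention, with rRMSE relative to the
reference mean and R² from the OLS of estimate on reference.

## Spatial correction and quantitative genetics

Plot values are corrected with

    value ~ f(x, y) + random(row) + random(range) + genotype (fixed),

where `f` is a tensor-product B-spline surface with second-order difference
penalties and ceil(2/3 · plots-per-direction) segments per direction.  This
is a deliberate simplification of a full PSANOVA decomposition: it keeps
the property that matters (smooth spatial denoising with an unpenalised
planar nullspace) at a fraction of the complexity.  Smoothing is selected
by generalized cross-validation over a log grid with an inflation factor
γ = 1.4 on the effective degrees of freedom — the standard guard against
undersmoothing, chosen here because an overfitted surface deflates the
residual variance and inflates repeatability.  Corrected values are
genotype BLUE + residual.

Repeatability and heritability are generalized heritabilities in the Cullis
form, `H² = 1 − v̄_ΔBLUP / (2σ̂²_g)`, computed from a one-random-effect
(genotype intercept) REML fit with the variance ratio profiled by bounded
1-D optimisation (tolerance 10⁻⁸, components floored at 0).  The full
prediction-error-variance matrix of the BLUPs is formed explicitly, so the
pairwise-difference variance includes BLUP covariances.  On balanced,
trend-free designs this reduces to the classical `σ²_g/(σ²_g + σ²_e/r)`.
Models: within-environment `Y = R | G` (replication fixed); across
environments `Y = Yr/R | G` when two or more replications remain, else
`Y = Yr | G`, on the genotype set common to all year-sites, with optional
subsampling to one or two replications for comparability with manual
protocols.  Genotype-by-year interaction is not separately modelled.

Relative efficiency of indirect selection is
`RE = h_HTFP · r_G / h_manual`; a zero manual heritability yields an
infinite RE with a flag rather than an error.

## The synthetic field

The simulator provides ground truth for every stage from first principles
of cereal ontogeny:

* main-stem leaves `N_l,MS = (GDD − t0)/P` with phyllochron `P` in °C·day
  per leaf.  (Writing the relation as a product of `P` and thermal time
  would be dimensionally inconsistent with `P` in °C·day per leaf, so the
  rate form is used.)
* tiller n carries `a·N_l,MS − b·n` leaves and exists only while that is
  positive; `a = 1.0, b = 2.5` by default so the first tiller appears after
  about three main-stem leaves, standard wheat ontogeny.  These constants
  have no published consensus values and are fully configurable.
* plot leaf area `LA = Σ_plants A_l · (N_l,MS + Σ_n N_l,Ti_n)` with equal
  single-leaf area `A_l` before stem elongation
  (`A_l = L × W × 0.835` from leaf length and width).

Genotype parameters are drawn once per trial from ranges representative of
an elite winter-wheat panel: phyllochron 70–80 °C·day, emergence
75–140 °C·day, single-leaf area 300–380 mm², GS30 spread 20 days by
default.  Thermal time accrues at 6 °C·day per calendar day, typical of the
early-spring tillering window at temperate sites, and campaigns are
scheduled two per week ending shortly after the last genotype's GS30.
Sowing rows are 0.125 m apart; plants are placed by a Poisson process
(18–50 plants m⁻¹ per plot, emulating variable emergence) with a clumping
fraction of close satellites.

Rendering stamps each plant as a flat-top disk whose area equals its
current leaf area; per view, the disk centre is jittered by a zero-mean
offset whose magnitude models leaf erectness under the view's zenith angle.
Averaging many views then produces exactly the fractional-cover signature
the method exploits; with zero jitter the aggregate is binary.  The
`percentile_trajectories` helper additionally provides an idealised,
directly parameterised percentile signal (staggered logistic curves of
ΔGDD) for testing the GS30 regressor in isolation.

What the simulator does *not* emulate: real leaf geometry and occlusion,
radiometric variation, soil background structure, shadows, tiller abortion
after GS30, and the segmentation errors of real imagery.  Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under controlled conditions — not field-level accuracy, which
depends on flight geometry, segmentation quality and reference data.

## Problem sizes

Desk-scale defaults were chosen so the full test suite and the end-to-end
fixture stay comfortably small: the fixture trial is 4 genotypes × 2
replications × 12 campaigns rendered at 2 mm effective GSD with 12 views
per plot/campaign; statistical simulations use 36 genotypes × 2
replications with ~8 Monte-Carlo repetitions; watershed validation uses 50
simulated plots; dynamics recovery uses 100 plots.

## Known limitations

* The P-spline surface approximates, but is not, a full PSANOVA/SpATS
  decomposition; variance components attributable to the smooth surface are
  not separated into ANOVA terms.
* The Cullis estimator ignores uncertainty in the estimated variance
  components themselves.
* The GS30 regressor memorises trial-specific appearance; grouped
  cross-validation (by genotype, by year-site) is reported precisely
  because transfer across environments is the known weak point of such
  models.
* Watershed counting degrades once canopies merge; calibration is only
  meaningful in the pre-GS30 window and the (a_W, b_W) relation is
  trial-specific.
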