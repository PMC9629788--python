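# Methods

`cropsail` couples a crop-growth trajectory model to a canopy radiative
transfer (RT) model so that synthetic training data for trait retrieval carry
biological constraints, and quantifies what those constraints buy across
retrieval methods, wavelength ranges and observation-geometry usage. This
note records the models, their assumptions, the numerical choices, and what
the synthetic study conditions do and do not demonstrate.

## The coupling transform

Each daily crop state (total and dead leaf area index `LAI_total`,
`LAI_dead`; leaf dry weight `LDW`, g m⁻²; canopy nitrogen `CNC`, g m⁻²;
decimal Zadok score `Zs`) is mapped to the RT model's leaf/canopy inputs by
fixed empirical relations:

| quantity | relation | units |
|---|---|---|
| specific leaf area | SLA = 10·LAI_total/LDW | cm² mg⁻¹ |
| mesophyll structure | Ns = (0.9·SLA + 0.025)/(SLA − 0.1) | – |
| water content | Cw = −0.000196·Zs + 0.0298 if f_dead = 0, else 0.0223·e^(−1.90·f_dead) | g cm⁻² |
| dry matter | Cm = 10⁻⁴·LDW/LAI_total | g cm⁻² |
| chlorophyll | Cab = 26·LNC, LNC = CNC/LAI_total | µg cm⁻² |
| carotenoids | Car = 0.216·Cab | µg cm⁻² |
| hot spot | hspot = a/LAI_total, a = 0.5 | m m⁻¹ |

with f_dead = LAI_dead/LAI_total. Anthocyanins and brown pigment are 0, soil
brightness `psoil` = 1 (dry end-member), average leaf angle 50°, viewing
zenith 0 (nadir). Solar zenith and relative azimuth come from latitude, day
of year and apparent solar time via the standard declination/hour-angle
identities (δ = 23.45 sin(360/365·(284+DOY)), h = 15(AST−12),
cos SZA = sin L sin δ + cos L cos δ cos h, sin SAA = cos δ sin h / sin SZA).

Numerical/edge choices:

* The two Cw branches disagree in the limit f_dead → 0⁺ (0.0223 vs the
  Zs-dependent green branch). The branch is selected by `f_dead == 0`
  exactly, with no smoothing: fidelity to the printed relations over
  continuity.
* The Ns relation has a pole at SLA = 0.1 cm² mg⁻¹; states with SLA ≤ 0.1
  raise a domain error. Computed Ns outside the plausible leaf range
  [1, 3.5] (which requires SLA > 1.25 for Ns < 1) is *flagged* on the
  record, never clipped — clipping would silently reshape the dataset.
* The solar-azimuth arcsine is taken on the principal branch with the sign
  carried by the hour angle; no quadrant correction is applied. Inputs where
  |cos δ sin h| > sin SZA (high-latitude quadrant cases) raise an error
  rather than being clamped. Day 366 maps to 365.
* Pre-emergence states (LAI_total = 0) are excluded from coupling rather
  than assigned bare-soil spectra.

## Synthetic wheat trajectories

The trajectory generator stands in for a full crop model campaign. It
emulates only the co-variation structure the coupling consumes:

* green LAI rises logistically to a flag-leaf peak (`peak_lai`, default 6
  m² m⁻² at `peak_das` = 100 d) and declines exponentially to ~15% of the
  peak by season end (default 160 d);
* the dead-leaf fraction is 0 before `senescence_onset_das` (110 d) and
  rises monotonically (tanh) toward `max_dead_fraction` = 0.85;
* the Zadok score is a piecewise-linear monotone schedule (emergence ≈ 10,
  stem elongation 30 at 0.4·peak_das, flag leaf 39 at the peak, 90 at
  maturity) — only the Cw transform consumes it;
* SLA (default range 0.15–0.30 cm² mg⁻¹) and leaf nitrogen per area
  (1.0–2.5 g m⁻²) are drawn **once per trajectory** with 2% day-to-day
  noise, keeping within-trajectory trait correlations strong — which is
  precisely what the constrained dataset is meant to carry;
* records are sampled fortnightly (`sampling_interval` = 14 d) from
  emergence, each at three apparent solar times (10:00, 12:00, 14:00),
  with the day of year advancing from the sowing day (default 1 May at
  latitude −27.54°).

Campaigns jitter peak LAI (0.45–1.1×), peak timing and senescence onset per
trajectory to emulate site/season/cultivar variation. What the generator
does **not** emulate: weather- and management-driven dynamics, water/N
stress, tillering/anthesis process detail, or measurement noise. Tests
passing on this generator therefore demonstrate the *mechanism* of
biological constraints under ideal forward-model agreement, not field-level
accuracy.

## The forward model

The canonical PROSPECT-D + 4SAIL distribution can be wrapped behind the same
interface when installed, but the shipped default is `PlateSailModel`, a
self-contained model authored for this package:

* **Leaf optics.** A generalized plate stack. One plate combines
  Beer–Lambert absorption (per-plate optical depth = Σ contentᵢ·kᵢ(λ)/Ns)
  with a diffuse external surface reflectance and a much larger internal
  interface reflectance, r_int = 1 − (1 − r_ext)/n², from total internal
  reflection — the mechanism behind the leaf's strong near-infrared
  scattering. The stack of a continuous number Ns ≥ 1 of plates is closed
  in form via the unit-determinant transfer matrix and the identity
  M^N = (sinh Nφ / sinh φ)·M − (sinh (N−1)φ / sinh φ)·I, cosh φ = tr(M)/2.
  The specific-absorption spectra kᵢ(λ) are smooth parametric curves
  (Gaussian pigment bands at ~420/470/640/675 nm for chlorophyll and
  400–520 nm for carotenoids; log-interpolated water anchors peaking at
  970, 1200, 1450, 1940 and 2500 nm; dry-matter features through the SWIR)
  authored in-code — they reproduce the qualitative spectral physics, not
  any published coefficient table.
* **Canopy.** Nadir reflectance is composed of (i) single scattering from
  sunlit foliage with a hot-spot gap-correlation kernel
  P_so(l) = exp(−(k_s+k_o)l + √(k_s k_o)(1−e^(−al))/a), a = tan SZA/(hspot·LAI),
  integrated with 32-point Gauss–Legendre quadrature; (ii) directly viewed
  sunlit soil; (iii) the multiple-scattering residue of an analytic
  two-stream solution (collimated source, Lambertian soil boundary) with
  its own first-order part removed to avoid double counting, treated as
  isotropic. Extinction uses the Ross G-function for a fixed 50° leaf
  inclination with random azimuth. Output is clipped to [0, 1]; only nadir
  viewing is supported (the framework fixes VZA = 0).
* **Soil.** Parametric wet/dry end-members (brightness rising with
  wavelength, water dips at 1450/1940 nm); `psoil` interpolates between
  them, 1 = dry. The same soil spectrum feeds the imagery module's
  background substitution.

Because train and test data are generated by the same forward model, every
retrieval result in this package is an *internal-consistency* experiment,
as in any synthetic-data inversion study; the model's contract (2101-point
grid, [0, 1] bounds, determinism, correct monotone responses to LAI,
chlorophyll and water) is what the tests pin down.

## cdata and rdata

`build_cdata` runs the forward model on the coupled rows as-is. `build_rdata`
independently permutes each varying column group across records —
(Ns), (Cw), (Cm), (Cab, Car), (LAI, hspot), (SZA, RAA) — and regenerates all
spectra. Permutation (rather than fitting and resampling marginal densities)
preserves every marginal exactly while destroying the inter-trait
associations; deterministically linked columns travel with their parents so
recombined rows still satisfy the formula identities. Under the permutation
null the sd of a Pearson correlation is 1/√(n−1), which sets the scale for
"association broken" assertions.

## Retrieval methods

All methods predict the four traits (LAI, Cab, Cm, Cw) jointly from
standardized features (zero-mean normalization read as full
standardization — centering plus unit variance — with a `center_only`
switch; angles are standardized like reflectance when included):

* **LUT** — cost = RMSE between normalized feature vectors; the estimate is
  the unweighted mean of the traits (physical units) of the k = 10
  lowest-cost training records, ties broken by stored order. Averaging k
  best entries is a regularization of the ill-posed inversion: on the
  unconstrained rdata it improves every trait relative to k = 1, while on
  dense noiseless cdata — already regularized by the biological
  constraints — k = 1 is near-exact and averaging can only add bias. The
  k-non-degradation property is therefore asserted on rdata.
* **RF** — one multi-output ensemble of 200 trees, leaf size 1,
  floor(log₂ n_features) features per split.
* **FFNN** — a fully connected 256×256×256 rectified-linear network,
  squared-error loss, adaptive-moment optimizer at learning rate 0.001, up
  to 1000 epochs with early stopping on a 10% validation slice and patience
  20, restoring the best weights. Implemented with scikit-learn's
  multilayer perceptron.

## Experiment grid and metrics

60 experiments: {cdata, rdata} × {with, without angles} × five wavelength
ranges (VNSWIR 400–2500, VIS 400–750, SWIR 1000–2500, VNIR 400–1000 nm —
interval endpoints inclusive, so VIS has 351 narrow bands — and mVNIR, the
five camera bands) × {LUT, RF, FFNN}. Camera bands default to boxcar
responses over the published MicaSense RedEdge limits (blue 465–485, green
550–570, red 663–673, NIR 820–860, red-edge 712–722 nm); measured response
curves can be supplied as CSV. Band resampling is the response-weighted mean
ρᵢ = Σφᵢⱼρⱼ/Σφᵢⱼ.

Each cell splits 75/25 (one split per variant, shared across cells at a
given seed; 4-fold cross-validation is available), fits, and reports per
trait: Pearson r, RMSE, RRMSE = 100·RMSE/mean(observed) (normalization by
the observed mean, with a `range` switch), and the OLS slope/intercept of
prediction on observation.

## Imagery loop

NDVI = (NIR−Red)/(NIR+Red); pixels with NDVI ≥ threshold count as vegetation
(boundary inclusive; stage-dependent thresholds of 0.5/0.65/0.75 are the
reference operating points). Background pixels are replaced by the model
soil reflectance resampled to the camera bands; plot rectangles are
half-open [min, max) in 0-based pixel coordinates, trimmed by a margin, and
the background-corrected map (soil-substituted pixels included, with a
`vegetation_only` alternative) is averaged per plot before prediction.
`synth_field` renders closed-loop scenes whose vegetation pixels carry
forward-model band reflectance; GeoTIFF ingestion is optional (via
tifffile) and untested against real UAV products.

## Problem sizes and determinism

Test and acceptance runs use desk-scale campaigns chosen to make the
mechanisms measurable while keeping the suite quick: ~700 coupled records
for unit-level properties, 1000 records for association-breaking checks,
~5000 records (145 trajectories × fortnightly sampling × 3 solar times) for
neural-network trait recovery, ~2100 records × 5 seeds for the
constrained-vs-unconstrained water-retrieval comparison, and 24 plots for
the imagery loop. Every stochastic step (trajectory jitter, permutation,
splitting, model initialization) is seeded; identical seeds give bitwise
identical datasets and predictions.

## Known limitations

* The shipped forward model is not the canonical PROSAIL; absolute
  reflectance values and retrieval accuracies are not comparable to studies
  using the published coefficient tables. The interface accepts the
  canonical implementation where available.
* The Cab–nitrogen and Ns–SLA relations are single fixed calibrations; the
  trajectory generator inherits their domain of validity.
* Only nadir viewing and a fixed 50° leaf angle are supported; the
  LAI-leaf-angle ambiguity of the inversion is deliberately frozen out.
* The azimuth identity is principal-branch only (see above).
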