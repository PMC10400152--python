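# Methods

## The estimation problem

Each sample is a leaf with a reflectance spectrum R(λ) ∈ [0, 1] on the
350–2500 nm grid at 1 nm (2151 points) and up to nine laboratory traits:
nitrogen, phosphorus, potassium, magnesium, calcium and sulfur content (%
of dry matter), leaf water content LWC = (FW − DW)/FW × 100 (%), chlorophyll
content CHL (µmol m⁻²), and leaf mass per area LMA = DW/LA (g m⁻²).
Replicate scans of a leaf are averaged pointwise before anything else; all
spectra are then binned into contiguous 10 nm windows (mean per window;
the trailing 1-point window at 2500 nm is kept and averaged over the points
it contains, giving 216 bands). Per trait, a regression model maps the
binned spectrum to the trait value.

## Regression engines

**PLSR.** Partial least-squares regression is implemented as PLS1 (one
trait at a time) with NIPALS deflation. Predictors and response are
mean-centered; predictors are not scaled to unit variance, since all bands
share reflectance units. Each component takes the weight vector
w ∝ Xᵀy (unit norm), scores t = Xw, loadings p = Xᵀt/tᵀt, q = yᵀt/tᵀt, and
deflates X ← X − tpᵀ, y ← y − qt. The regression coefficients are
B = W(PᵀW)⁻¹q, so prediction is affine in the spectrum. When the centered
predictor matrix runs out of rank, extraction stops early and models
requested with more components predict identically to the rank-limited
one. At full rank the predictions coincide with ordinary least squares
(checked against the normal equations and against an independent PLS
implementation in the test suite).

Fitting accepts an optional nonnegative sample-weight vector; integer
weights reproduce physical row replication exactly (weighted means and
weighted inner products throughout), which gives a memory-efficient
equivalent of extra-weighted spiking.

**MLP.** The nonlinear comparator is a single-hidden-layer relu network
with L2 penalty, trained by L-BFGS on standardized predictors and response
(stopping at loss-change 1e−6 or 2000 iterations), deterministic at a fixed
seed. Scalar hidden sizes {5, 10, 15, 20} crossed with penalties
{0.005, 0.01, 0.03} form the tuning grid. Predictions are computed by a
forward pass from the stored weights and returned in original trait units,
which makes persistence (versioned JSON) and prediction independent of the
training backend.

## Hyperparameter selection

Per trait and method, 10-fold cross-validation: samples missing the trait
are excluded first, folds are a random near-even partition (sizes differ by
at most one), and all grid points share the same assignment. Out-of-fold
predictions are pooled across folds and RMSE_CV / R²_CV computed once on
the pooled vector; pooled RMSE_CV equals the square root of the
fold-size-weighted mean of per-fold MSEs (tested as an identity). The
chosen point minimizes RMSE_CV; exact ties go to the smaller model (fewer
latent variables; smaller hidden size, then smaller penalty). The final
model is refit on the whole calibration set at the chosen point. PLSR
latent variables run 1–30 by default; grid points infeasible at the fold
size (n_lv > min(n_train − 1, p)) are skipped with a warning. Folds are
plain random; a species-stratified variant was considered and left out
because the analysis never requires it — fold seeds are explicit instead.

## Transfer by extra-weighted spiking

From each external set, `n_spike` samples (default 20) are drawn uniformly
without replacement; the rest form the test set, which never enters any
calibration. Three schemes are calibrated and evaluated on that test set:
the library alone, the spike set alone, and the library augmented with each
spike sample replicated r = round(n_library/n_spike) times (round-half-up,
minimum 1, so 2460/20 gives exactly 123 and the balanced case gives plain
concatenation). Replicates are physical rows with suffixed ids; the
weighted-fit equivalent is exposed separately and tested to give identical
PLSR coefficients. Each scheme re-tunes hyperparameters on its own
calibration set. A leakage guard asserts on every run that no test id
(including replicate origins) occurs in the calibration set.

The spike-size sweep holds aside one pool (default 50 samples) from the
external set, then for each size in {10, 20, 30, 40, 50} spikes the library
with a random pool subset and evaluates on the external samples outside
the pool, so all sizes share one evaluation set.

## Evaluation conventions

R² is the coefficient of determination 1 − SSE/SST about the observed mean
(not squared correlation); on external sets it can be negative and is never
clipped. bias = mean(predicted − observed). RPD = SD(obs, n−1 denominator)
/ RMSE, the standard chemometric convention; it is undefined (reported as
such, not as a number) when RMSE = 0. The PCA diagnostic is mean-centered
PCA of the spectra with per-group scores for 95% ellipses — domain shift
appears as separated group centroids in PC1–PC2.

## The synthetic-study generator

The real calibration currency of this analysis — a multi-thousand-sample
leaf spectral library — is not publicly deposited, so the package includes
a generator that emulates the statistical structure the analysis depends
on. It is a feature-based surrogate, not radiative-transfer physics:

* **Archetypes.** Each species has a smooth baseline built from a VIS
  floor, a green-peak Gaussian at 550 nm, a sigmoidal red edge at 710 nm,
  and fixed water/SWIR depressions. Default shapes differ between the
  library species (maize- and sorghum-like monocots) and the external
  species (soybean- and camelina-like eudicots).
* **Trait coupling.** Reflectance = clip(baseline + shift −
  Σ sensitivity·trait·Gaussian(center, σ) + noise, 0, 1). Band placements
  follow leaf spectroscopy: chlorophyll absorbs at 430/660 nm, protein-bound
  N at 1510/1680/2180 nm, water at 1190/1450/1940 nm, LMA brightens the NIR
  plateau (negative sensitivity at 900 nm) and absorbs at 2300 nm, with
  weaker indirect bands for P, K, Mg, Ca, S. Sensitivities are set so the
  mean-trait band depths are a few percent reflectance.
* **Trait distributions.** Truncated multivariate normal per species
  (rejection sampling on physical bounds: percentages in [0, 100],
  CHL/LMA ≥ 0), with a fixed correlation structure dominated by the strong
  N–CHL association (0.8; roughly half of leaf N sits in chlorophyll),
  protein-driven N–S (0.55), and Mg–CHL (0.35), completed with weaker
  second-order terms required for positive semidefiniteness. Library means
  (e.g. N 2.5 ± 0.7 %, LWC 78 ± 5 %, CHL 450 ± 110 µmol m⁻²,
  LMA 55 ± 12 g m⁻²) are assumptions chosen to put RMSEs on realistic
  scales — the source study does not publish its trait covariances — and
  are configuration, not constants.
* **Domain shift.** External species get (i) an additive smooth offset
  (species-fixed mixture of a NIR sigmoid and two broad Gaussians, up to
  ~±0.05 reflectance) and (ii) multiplicative perturbation of every band
  sensitivity (up to ±50%), both scaled by one `shift_magnitude` knob
  (0 disables the shift entirely). External trait means shift by 0.4 SD
  and SDs inflate by 25%.
* **Noise.** White per-point scan noise (SD 0.004) plus smooth per-sample
  structured variation (SD 0.012): a random cubic trend and eight random
  broad Gaussian bumps, emulating probe-contact and leaf-surface effects.
  The structured component is the load-bearing nuisance: it is
  high-dimensional enough that a 20-sample calibration set cannot average
  it out while a few-hundred-sample library can, which reproduces the
  qualitative transfer regime the analysis studies (library-only models
  degrade on shifted externals, spike-only models overfit, the
  extra-weighted spiked library recovers most of the loss, and sweep gains
  level off near spike size 40–50).

Everything is bit-for-bit reproducible from the configuration seed
(`numpy` SeedSequence children per dataset). Masked traits (the
camelina-like set lacks CHL and LMA) are generated — the leaf has them and
they shape its spectrum — but recorded as missing.

**What passing tests on this generator do and do not show.** They show the
pipeline is correct (no leakage, correct selection, correct weighting) and
that it detects and repairs domain shift of the modelled kind: smooth
additive offsets, band-sensitivity changes, and mean shifts. They do not
certify performance on real leaves, where nuisance structure is richer
(instrument drift, surface moisture, developmental stage) and trait–spectrum
coupling is nonlinear near saturation.

## Study layouts and problem sizes

Two stock layouts are provided. `full_study_config()` reproduces the full
design of the motivating study — seven library datasets totalling 2460
samples (maize, sorghum; 2018–2020; field and greenhouse) and four external
sets totalling 445 (soybean 126, camelina 96, maize 163, sorghum 60) — and
is used for structural accounting. `demo_config()` is the desk-scale
workhorse used by the test suite and the acceptance script: a 240-sample
two-species library with soybean-like (n=126) and camelina-like (n=96)
externals, chosen so that repeated multi-seed pipeline runs complete in
minutes on one CPU while preserving every structural feature (two library
species, shifted externals, one external set missing CHL/LMA). Property
suites on it use a 1–12 latent-variable grid, matching the low intrinsic
dimension of the generated signal.

## Numerical choices and edge cases

* Reflectance is stored as a fraction; files whose values exceed 1.5 are
  rejected with a percent-scale hint rather than rescaled silently.
* Coarse-grid CSV headers carry the window-center wavelength
  (`wl_c0355`-style, one decimal kept when the center is non-integer, e.g.
  `wl_c0354.5` for the first full 10 nm window) so read∘write is the
  identity up to 6-significant-digit float formatting.
* NIPALS stops when the residual covariance norm falls below 1e−12 of the
  initial predictor scale; fitted arrays are built identically whatever the
  requested component count, so rank-exhausted models are bitwise equal and
  the parsimony tie-break deterministically recovers the generative
  dimension on noiseless data.
* Zero-variance responses (whole set, or any CV training fold) raise named
  errors instead of producing degenerate latent variables.
* A trait entirely missing from an external set yields an "unavailable"
  result object, never a zero.
* `derive_lwc` rejects DW > FW as a data-entry fault; `derive_lma` converts
  cm² to m² internally.
* All pipeline randomness derives from one root seed via
  `derive_seed(root, stage_name)` (CRC-based, < 2³¹), so a subcommand rerun
  reproduces its state inside a full run.

## Known limitations

The generator's linear trait–band coupling understates real nonlinearity
(saturating absorption at high chlorophyll); the clip to [0, 1] is the only
nonlinearity. The MLP is a deliberately small single-hidden-layer stand-in
for deeper architectures (a depth option is out of scope). Spike selection
is uniform random; stratified, Kennard–Stone or Latin-hypercube selection
would likely improve small-spike transfer and is left as a pluggable
extension point. Instrument drift and white-panel recalibration are not
modelled.
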