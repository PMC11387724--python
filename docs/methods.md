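# Methods

## Spectra and colorimetrics

All computation runs on the canonical integer-nanometre grid 300–700 nm
(401 points), the working range of UV–VIS reflectance spectrometry.
Measured spectra on other grids are linearly interpolated onto it; replicate
specimen spectra are averaged per (species, sex, patch) *before* visual
modelling.  Reflectance is stored as a fraction; percent input is detected
(values > 1.5) and divided by 100.  A positivity floor of 1e-5 is applied at
regridding so that log quantum-catch ratios downstream are always defined.

Colorimetric variables: total brightness B1 = Σ R(λ); mean brightness
B2 = B1/401 (the B-label pair is kept explicit because the two statistics
differ only by the constant 401 and are easily conflated — both are
exposed); hue H1 = argmax R(λ), ties broken toward the lowest wavelength for
determinism; segment chroma S1[band] = band sum / B1 with inclusive integer
endpoints for the bands U 300–400, V 300–415, B 400–510, G 510–605,
Y 550–625, R 605–700 nm.  The bands deliberately overlap, so Σ S1 can
exceed 1; each S1 lies in [0, 1] and the full-range chroma is exactly 1.

## Visual model

Cone spectral sensitivities use the Govardovskii A1 alpha-band template with
the standard constants (A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922,
c = 1.104, and the λmax-dependent a-term) plus the UV beta band, peak
normalized.  The default receptor set is an average UVS system — λmax
{372, 456, 544, 609} nm, relative densities {1, 2, 2, 4}, Weber fraction
0.1 referenced to the most abundant (longest-wavelength) cone — and is fully
configurable, since published "average UV-type" systems differ in detail;
all JND outputs are conditional on these settings.

Quantum catches are plain grid sums Σ R·I·S (on a uniform 1-nm grid the
difference from trapezoidal integration is an endpoint term that cancels in
every log-ratio used).  The illuminant defaults to the idealized flat
spectrum; alternatives are accepted as an array.  Catches are raw (not
simplex-normalized): the receptor-noise model works on log-ratio signals,
which are undefined after normalization to unit sum.

The distance is the chromatic receptor-noise limited ΔS for any number of
receptor channels n ≥ 2 (the generic opponent formula; for n = 4 it reduces
to the standard tetrachromatic expression, for n = 2 to
|Δf₁ − Δf₂|/√(e₁² + e₂²)).  No achromatic (double-cone) channel is modelled:
the analysis consumes a single chromatic JND per patch and pair.  The pair
matrices are computed vectorized from the n_species × n_cones log-catch
matrix and symmetrized exactly; the whole-body matrix is the element-wise
mean over the six patch matrices.

## Geography

Ranges are simple (possibly multi-part) polygons.  Planar mode (default for
synthetic data, exact closed forms under test) uses Euclidean geometry;
lon/lat mode computes minimal distances as great circles on a spherical
Earth (R = 6371 km) over boundaries densified to ~0.05°.  Intersection
areas and both directional overlap fractions are exact polygon operations.

Sympatry is a single consistent rule: positive intersection area.  Ranges
that merely touch along a boundary (zero distance, zero area) are classified
allopatric; the invariant "sympatric ⇔ min distance 0 ⇔ overlap > 0" then
holds everywhere except that degenerate touching case, which has measure
zero under the synthetic generator and is called out rather than modelled.
Minimal distance between sets is not a metric (no triangle inequality is
asserted).

## Niche overlap

Schoener's D is computed on same-grid rasters after normalizing each surface
to sum 1: D = 1 − ½ Σ|p − q| = 1 − TV(p, q).  The "NDVI-only" and
"all-variables" overlaps are two separate single-layer suitability surfaces
per species (mirroring one fitted niche-model surface per variable set); no
attempt is made to compose multi-layer products.  Mean NDVI per species is
either the unweighted mean over cells whose centres fall strictly inside
the range polygon (boundary cells excluded — deterministic under exact
geometry) or the suitability-weighted mean Σ pᵢ·NDVIᵢ.  Rasters are plain
ESRI ASCII grids; there is no binary raster support.

## Phylogeny

Trees are rooted Newick with branch lengths in My; polytomies are handled
natively.  Ultrametricity is checked at tolerance 1e-6 × depth and flagged.
Pairwise "phylogenetic distance" defaults to divergence time (patristic/2)
on ultrametric trees, because divergence time is the quantity the predictor
represents; raw patristic distance is available by flag (the factor 2
affects effect-size magnitude, never sign or significance).  The PGLS
covariance is built from the additive-distance identity
C[i,j] = (depthᵢ + depthⱼ − dᵢⱼ)/2, so it is consistent with the distance
matrix by construction.  Pagel's λ multiplies off-diagonal entries only.

## Pairwise GLS

The pair table holds one row per unordered species pair.  The geographic
predictor is partition-specific: 0/1 sympatry in the full table, range
overlap among sympatric pairs, minimal distance among allopatric pairs.
The two directional overlap fractions are aggregated by their mean by
default (max / min / species-1 are config options) — the directional values
are both retained in the table.

Models are `response ~ phylo + geo + niche` without interactions, fitted
with an identity correlation structure (coefficients coincide with OLS/ML).
Continuous predictors are z-scored so coefficients read as standardized
effect sizes; the 0/1 indicator stays on its native scale; the response is
left unstandardized by default so that simulation truths are recovered on
their own scale (a `standardize="both"` option z-scores it too).  Tests are
two-sided t with n − k df.  VIF per predictor is 1/(1 − R²) from regressing
it on the other two.

Rows sharing a species are not independent; no pairwise-covariance
correction is applied (matching standard practice for this design), and a
Mantel-style permutation correlation (species-label permutations, 999 by
default) is provided as a robustness flag.  This is a known limitation:
nominal GLS p-values on pair data are anti-conservative to a degree that
grows with the imbalance of species' pair counts.

## PGLS

GLS with error covariance σ²·C(λ).  Fixed mode uses λ = 1 (pure Brownian);
ML mode maximizes the profile log-likelihood (ML, not REML) over λ ∈ [0, 1]
by bounded scalar search at tolerance 1e-6, with the endpoints evaluated
explicitly so boundary optima are reported at the boundary.  Standard
errors use the unbiased σ̂² (n − k denominator); the fixed-λ path is
verified against the R nlme/ape implementation to 1e-8, and the ML path
against a dense λ-grid scan of the same likelihood.  λ is deliberately
constrained to [0, 1] (some implementations allow λ > 1 up to the feasible
maximum; the bounded version is the conventional, always-PSD choice).

Benjamini–Hochberg correction is applied within each output table —
per (sex, partition) for the GLS tables and per (lambda-mode, patch) family
for the PGLS tables — with a config switch for global pooling; the family
choice is a genuine analytical degree of freedom and is therefore explicit.

## Synthetic data

The generator's defaults mirror the real study system's scale: 106 species,
a 20 My radiation (a realistic crown age for a large passerine radiation),
six patches × two sexes × 2 specimen replicates, and a target sympatric
pair fraction of 0.31.  Spectra are Gaussian peaks R(λ) = 0.05 + 0.9h·
exp(−(λ−μ)²/2·40²) whose peak wavelength (tip SD 60 nm around 500 nm,
reflected into [310, 690]) and height (SD 0.15 around 0.45) evolve as a
√s·BM + √(1−s)·iid mix with phylogenetic-signal weight s per patch (default
0.8); replicates add N(0, 0.01) measurement noise and values are clipped to
[1e-5, 1].  Trees are pure-birth with one extra common waiting time added
to every tip branch (the simulator stops at the last speciation event,
which would otherwise leave two zero-length tips and a singular Brownian
covariance), then rescaled to the target depth.  Ranges are 48-gon circles
with radii uniform in [6, 16] on a 100-unit landscape, centred by a
three-cluster Gaussian process whose spread is bisected until the realized
overlap fraction is within 0.1 of target (reflected, not clipped, into the
landscape — clipping piles centres onto corners).  NDVI is a west–east
gradient 0.2 + 0.6x/L plus smoothed seeded noise (amplitude 0.15), clipped
to [0, 1]; suitability surfaces are Gaussian bumps at range centroids with
width 0.8 × range radius, the all-variables variant modulated by a shared
smooth environment layer.

For regression-recovery tests the pair response is simulated *directly* as
β₁z(phylo) + β₂z(geo) + β₃z(niche) + N(0, σ²) (default β = (−1, −0.5, 0.3),
σ = 1): a JND matrix derived from evolved spectra has no closed-form
regression coefficients, so known-truth tests bypass the spectral layer on
purpose, while the spectral layer is validated separately (high signal →
colour distance tracks relatedness; zero signal → Mantel correlation with
phylogenetic distance ≈ 0).  Direct pair responses are not constrained to
be embeddable as a distance matrix.

What the generator does *not* emulate: iridescence and angle-dependent
reflectance, structural-colour spectra with multiple peaks, range shapes
other than discs, spatial autocorrelation between NDVI and species ranges,
and any selection-driven covariance between colour and sympatry or niche.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated generative model, not robustness to these real-data
features.

A single seed fans out via fixed per-stage substreams (tree, spectra,
ranges, rasters, response), so results are reproducible and stages are
independent of one another's draw order; every pipeline run writes a
manifest with the config hash and output checksums.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on synthetic data at
sizes chosen to exercise each code path with exact or simulation oracles:
pair-level GLS recovery at n = 200 pairs × 200 replicates (coverage) and
1000 replicates (null calibration); PGLS λ recovery on a 50-tip tree × 200
replicates per regime; geometry and Schoener's D identities on 100 random
polygon/raster pairs; end-to-end pipeline determinism at 30 species (435
pairs).  The full study scale (106 species, 5565 pairs) runs in a few
seconds and is covered by the flow-through tests.
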