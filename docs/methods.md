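# Methods

This note documents the models implemented in `ecazones`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical choices a maintainer should know about.

## Geostatistics

**Variogram estimation.** The experimental variogram is the
method-of-moments estimator γ̂(h_k) = (1/2N_k) Σ (z_i − z_j)² over
distance bins. Defaults when the caller gives none: lag width = twice
the mean nearest-neighbour spacing (so the first bins are well
populated on transect surveys), maximum lag = half the maximum pairwise
distance (beyond which the estimator is dominated by edge pairs). Bins
with no pairs are dropped. Directional variograms restrict pairs to an
angular sector; the anisotropy ratio is the max/min of the fitted
directional ranges, and isotropy is assumed below a ratio of 1.5
(configurable).

**Model fitting.** Only the spherical family (plus the pure-nugget
degenerate case) is fitted, by weighted least squares with Cressie
weights N_k/γ(h_k)², bounded nonnegative, with a 10-point multistart
over initial ranges and nugget fractions (L-BFGS-B). A fit whose
structured variance is < 0.1 % of the total sill is reported as pure
nugget with `range_identifiable = False`. Spatial-dependence strength
is classed by the nugget/total-sill percentage: ≤ 25 strong, ≤ 75
moderate, else weak. The variogram convention throughout is that "sill"
printed in field reports is the *total* sill c₀ + c; a nugget of 0.19
against a total sill of 0.73 gives the 26 % ratio the class boundary
refers to.

**Kriging.** Ordinary kriging in semivariance form: per target, the
(n+1)×(n+1) system [γ_ij, 1; 1ᵀ, 0][w; μ] = [γ_i0; 1]. The local mean
m(x) is an unknown constant eliminated by the Σw = 1 constraint and is
never stored. The kriging variance is Σ wᵢγ_i0 + μ, clipped at zero
with a warning (tiny negative values arise from round-off). The default
neighbourhood is the 16 nearest points within 1.5× the range — a
practical moving-window compromise; with `max_neighbors ≥ n` the result
equals the full single-system solve (tested to 1e-8). Duplicate
coordinates are averaged before any solve; otherwise the system is
singular. Because γ(0) = 0 on both the diagonal and the right-hand side
at a co-located target, the predictor honours data values exactly even
with a nonzero nugget (the nugget is attributed to measurement at
distinct locations). Leave-one-out cross-validation reports RMSE, mean
error, mean kriging SE, the mean standardised error (≈ 0 when unbiased)
and the mean standardised *squared* error (≈ 1 when the variogram is
calibrated), plus the RMSE-below-data-SD effectiveness flag.

**Normality** of the survey is summarised (skewness, kurtosis, CV) but
never enforced; kriging does not require it.

## Zoning

ECa (mS/m) and elevation (m) are incommensurable, so layers are
z-scored over jointly valid cells before clustering; the stored
means/SDs invert the transform. Clustering is an iterative
self-organising means procedure: k-means with *deterministic* initial
centres at evenly spaced quantiles along the first principal axis of
the feature cloud (no random initialisation), split/merge moves
disabled because k is fixed by design (two or three zones are what a
grower can manage). The converged clusters provide Gaussian signatures
(mean, covariance) to a maximum-likelihood classifier with equal priors;
ties break to the lowest class index, and near-singular covariances are
ridge-regularised with a warning. Zones are relabelled by ascending
zone-mean ECa so that label 1 is always the least productive zone.
A 3×3 majority filter is available but off by default; fragmented
productive cores are a genuine feature of conductivity maps and
smoothing them is an interpretive choice.

Validation samples are apportioned to zones by the largest-remainder
rule on area fractions with a floor of one sample per zone; in-zone
positions are uniform draws over the zone's cells with a fixed seed.

## Soil-fertility measurement (rating-scale model)

Nine properties are recoded to m = 5 ordered categories (category 1 =
lowest contribution to fertility). The default recoding is
equal-interval over each item's observed range; a quantile scheme and
externally supplied cut points are supported, and the applied cut
points are always exported so a recoding can be reproduced or injected.
Sand is reverse-scored (coarse texture ⇒ low water/nutrient holding);
all other items score positively.

The polytomous model is the Andrich rating scale — one difficulty d_i
per item and one set of thresholds τ_k shared across items — the
natural choice when every item uses the same 5-category design. With
the category index k = 1..m,

  P(X = k) ∝ exp Σ_{j≤k−1} (B − d − τ_j),

which at m = 2 reduces exactly to the dichotomous form
P = e^{B−d}/(1+e^{B−d}).

**Estimation** is joint maximum likelihood: damped Newton updates of
each person measure equating observed and expected raw scores,
alternating with bounded quasi-Newton (L-BFGS-B) maximisation over the
item difficulties and thresholds, until the largest score residual is
below 0.01 and the largest parameter change below 0.001 logits.
**Identification** needs two constraints, not one: mean(d) = 0 *and*
Στ = 0, because the likelihood is invariant to shifting all B and τ₁
together; the threshold constraint also makes the m = 2 case coincide
with the dichotomous model. Extreme raw scores (minimum or maximum
possible) have no finite ML estimate; they are excluded from
calibration, then measured from scores pulled 0.3 score points inward,
and flagged as extrapolated. Items observed in a single category are
dropped with a warning. Missing cells are treated as not administered
(excluded from score sums and estimating equations). No small-sample
bias correction is applied: JMLE measures are biased at small N, which
matters at a 20-sample field campaign — measures there should be read
comparatively, not absolutely.

Standard errors are the inverse square roots of the score information
(sum of model category variances). Threshold disordering is reported,
never forced away. **Fit diagnostics**: with z_ni = (X−E)/√W, Outfit is
the unweighted mean of z² and Infit the information-weighted
Σ Wz²/ΣW; extreme persons are excluded from item statistics and
zero-variance cells from all sums. The conventional acceptance band is
0.6–1.5.

## Validation statistics

Kruskal–Wallis with tie correction (p from χ² with k−1 df; the
all-identical degenerate case returns H = 0, p = 1). Dunn's pairwise z
uses the tie-corrected rank variance; for two groups z² equals H
exactly. No multiplicity adjustment is applied by default — the strict
α = 0.01 plays that role, matching common field-trial practice — with
Bonferroni and Holm available. The compact letter display uses
insert-and-absorb: start from one letter set containing all groups,
split on each significant pair, drop absorbed subsets; groups are
processed in zone order so output is deterministic. NDVI is
(NIR − Red)/(NIR + Red) from band-4/band-8 reflectances only; zonal
means resample the zone raster to the NDVI grid by nearest neighbour,
and a per-zone flag marks monotone seasonal decline.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical conditions the analysis
assumes: a field mean of 46.8 mS/m with a 58 % coefficient of
variation, a spherical variogram with range 130.4 m and a 26 % nugget
fraction, transect-style sampling with sensor noise and a 3 % rate of
corrupted readings (negated or ×10, logged so cleaning can be checked
exactly), proportional zone areas of roughly 0.35/0.45/0.20, and
fertility rising from the least to the most productive zone.

Two design decisions deserve emphasis:

* **Variance partition.** The stated CV and nugget fraction describe
  the *observed* field, and the concentric zone pattern is itself the
  dominant structured component of that field. The scenario therefore
  partitions total variance (mean·CV)² into between-zone variance
  (from ±31 mS/m zone offsets and the zone areas), an iid nugget share
  (26 % of total), and a correlated residual at range 130.4 m taking
  the remainder. Treating the CV as *within-zone* instead would double
  the total variance and make the zones unrecoverable from any map —
  inconsistent with a field whose zonation is visible in the kriged
  surface.
* **Topography.** The DEM is a gentle tilted plane (≈ 2 m of trend)
  with ±0.3 m undulation and a 2.5 m central depression co-located
  with the high-ECa core, because low ground accumulates water and
  fines; that co-variation is what makes elevation a useful zoning
  covariate at all. Total relief stays ≈ 3 m ("gentle").

Soil-sample chemistry is *back-constructed*: category ratings are drawn
from the rating-scale model at the sample's true fertility, then
continuous values are placed inside the matching category bin of
realistic per-property ranges, so recoding at the stored cut points
reproduces the drawn ratings exactly. The texture triple is closed to
sum to 100 % with silt absorbing the closure (its rating updated
accordingly). Consequences: inter-property correlations beyond the
shared latent factor (e.g. the clay–CEC link) are *not* emulated, no
physically based soil–ECa forward model connects the chemistry to the
conductivity field, and passing tests say nothing about sensor physics,
depth response or laboratory error structure. Recovery tests
demonstrate the *statistical machinery*, not agronomic truth.

Default problem sizes — a 60×60 grid of 10 m cells, 1 800-point
surveys, 20 soil samples for fixtures and 300 for Rasch recovery —
were chosen so a full pipeline run takes a few seconds while keeping
every estimator in its well-behaved regime; Rasch recovery uses N ≥ 200
because JMLE at N = 20 is too unstable for parameter-recovery
assertions (the 20-sample fixture is still exercised end to end).

## Numerical choices and degenerate inputs

* Gaussian fields: exact Cholesky up to 10⁴ cells (jitter ladder
  1e-10…1e-6), 2-D circulant embedding with clipped negative
  eigenvalues above that.
* Variogram fit: Cressie-weighted SSE, denominators floored at 1e-12.
* Kriging: singular neighbourhood systems fall back to least squares;
  variances clipped at 0 with a warning.
* Rating-scale likelihood: computed via log-sum-exp; item/threshold
  parameters bounded in ±30 logits.
* Raster I/O: ESRI ASCII with `repr`-precision headers and %.10g
  values — round-trips are exact in geometry and ~10 significant
  digits in values.
* Empty clusters: one re-seed with k-means++, then failure.
* Zero-range (constant) items, all-extreme matrices, collinear
  elevation points, empty zones and zero-denominator NDVI all raise
  `ValueError` with a specific message rather than propagating NaNs.

## Known limitations

* TIN gridding is approximated by Delaunay piecewise-linear
  interpolation; proprietary TIN edge rules are not reproduced.
* Only the spherical variogram family is supported; no universal or
  co-kriging.
* JMLE (not conditional/marginal ML); no differential item functioning.
* The pipeline treats subparcels jointly; per-subparcel runs are a
  caller-side loop with separate configs.
* No CRS handling: coordinates must arrive as planar metres.
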