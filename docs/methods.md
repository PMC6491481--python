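# Methods

This note documents the models implemented in `orchard-phenomics`, the
conventions that had to be pinned where the field literature leaves latitude,
the defaults of the synthetic-data generators, and what the test suite does
and does not establish about real data.

## Crown geometry

**Convex hull.** `c_volume` is the volume of the 3D convex hull (Qhull) of
the crown point cloud; it measures the maximal space occupation of the tree.
Clouds with fewer than four points, or coplanar/collinear clouds, are
rejected explicitly rather than returning a zero volume.

**Alpha hull.** `a_volume` is the volume of the 3D alpha shape: the union of
Delaunay tetrahedra whose circumscribing-sphere radius is strictly smaller
than α (metres). This "α = radius bound" convention — the one used by the R
`alphashape3d` family — is stated in every output because a published α value
is meaningless without it; under it `a_volume` is non-decreasing in α and
converges to `c_volume` as α grows. Volumes of disconnected components are
summed, since crowns fragment at small α. A published default of α = 0.15 m
is used when no calibration data are available; `select_alpha` reproduces the
calibration procedure (choose the grid value maximizing the Pearson
correlation between `a_volume` and measured total leaf area on a reference
subset) and reports the full correlation-vs-α profile. Degenerate tetrahedra
(volume below 1e-14) are given an infinite circumradius so no finite α
retains them.

**Convexity index.** `c_i = a_volume / c_volume ∈ (0, 1]` is a proxy for
foliage density within the crown envelope; `c_i → 1` for a compact convex
crown.

**STAR.** Each point of the cloud is rendered as an opaque disk of radius
`leaf_radius` facing the viewing direction; the silhouette area per direction
is obtained by rasterizing the projection plane (default cell size
`leaf_radius / 10`; the cell must be finer than the disk) and counting
covered cells. STAR is the mean over directions of silhouette area divided by
the total one-sided leaf area. Defaults: 46 upper-hemisphere directions on a
Fibonacci lattice (equal-area in cos(zenith); a single-zenith option exists);
`leaf_radius` = half the median nearest-neighbour distance when not supplied
(scale-free); the denominator is `n_points × π leaf_radius²` unless the true
leaf area is known (synthetic crowns pass their exact TLA). The rasterized
silhouette was checked against the exact union-of-circles area (shapely) to
within 2% at the default resolution.

## Imagery

**Thermal calibration.** Digital numbers are mapped to °C by an OLS line
through ground-target (DN, temperature) pairs; at least two targets with
distinct DN are required.

**Indices.** NDVI = (ρ850 − ρ675)/(ρ850 + ρ675); GNDVI uses the 570 nm green
band by default (530 nm is reserved for PRI; configurable, since a 6-band
camera carries two green bands); PRI = (ρ530 − ρ570)/(ρ530 + ρ570); MCARI2 is
the published improved chlorophyll absorption ratio on (ρ850, ρ675, ρ570).
Zero-denominator pixels become NaN rather than infinities.

**Per-tree statistics.** A tree's pixels are those whose centres fall within
a 0.70 m buffer around the trunk position (pixel-centre-in-circle membership;
unambiguous and testable). Temperature statistics (mean and sample n−1 SD of
T_surf − T_air) use vegetation pixels only (NDVI > 0.3 by default); spectral
index means use all buffer pixels. A buffer with no vegetation pixel yields a
missing value, not an error.

**WDI trapezoid.** The wet and dry edges are straight lines in
(NDVI, T_surf − T_air) space joining the saturated-soil to well-watered-
vegetation vertices and the dry-soil to water-stressed-vegetation vertices
respectively. WDI = (dT − T_wet)/(T_dry − T_wet) at the query NDVI, clipped
to [0, 1]; the per-tree WDI is evaluated at the tree's mean NDVI and mean dT.
The automatic fit takes the 5th/95th NDVI percentiles as the soil and
vegetation abscissae, traces the 2.5th/97.5th temperature percentiles per
NDVI bin, and regresses each envelope on bin-centre NDVI. Because an inner
quantile of a filled trapezoid sits inside the true edge by a fixed fraction
of the local height, the two quantile lines are linearly extrapolated back to
the 0/100% envelope under a uniform-fill assumption (`debias=True`); without
this correction the soil-edge vertices would be biased inward by ~0.5 °C at
realistic edge separations. A manual mode accepts the four vertex
temperatures (and optionally the two abscissae) directly, for vertices read
off a published scatter. The fit requires at least 100 pixels, an NDVI span
of at least 0.05 between the soil and vegetation abscissae, and three usable
bins.

## I_PL

ΦPSII = (Fm′ − Fs)/Fm′; J_PSII = ΦPSII × PPFD × a × f_PSII with leaf
absorptance a = 0.84 and PSII partition fraction f_PSII = 0.5, the widely
used leaf-level defaults (both configurable and recorded in model metadata).
K_O/K_C uses Arrhenius temperature responses with the standard in-vivo
reference constants (K_C: 404.9 µmol mol⁻¹, E_a 79.43 kJ mol⁻¹; K_O:
278.4 mmol mol⁻¹, E_a 36.38 kJ mol⁻¹); the ratio is taken on the constants'
native printed units (≈ 0.688 at 25 °C) — any fixed scale is absorbed by the
linear calibration, and a constant-ratio mode short-circuits the temperature
response entirely. Because E_a(K_C) > E_a(K_O), the ratio decreases with leaf
temperature.

Calibration is per device: gas-exchange devices differ in internal
fluorescence calibration, so coefficients do not transfer. A seeded random
2/3 of the records fits the OLS of A_n on P_KO/KC and (T_leaf − T_air) with
intercept; the held-out 1/3 provides validation R² (squared Pearson
correlation of observed vs predicted) and RMSE in A_n units. Stratification
of the split is not applied by default; the seed is recorded in the model
file. Predicting with a model on records from another device is an error.

## Quantitative genetics

Each trait is modelled as y = Xβ + Zg + e with g ~ N(0, σG² I) over
genotypes and e ~ N(0, σR² I). Variance components come from REML
(statsmodels MixedLM, with a derivative-free Powell polish after the default
optimizer: the gradient stop alone leaves ~1e-5 slack in the variance
components, and the balanced-design ANOVA oracle is matched to 1e-6 after
polishing). BLUPs are the conditional means of g. Model selection across
candidate fixed-effect structures (default set: scenario; scenario + date;
scenario + device + VPD) uses BIC computed from an ML refit of each
structure, because REML likelihoods are not comparable across fixed-effect
sets; the likelihood flavour is recorded on the fit. A genetic variance
estimated at the zero boundary is flagged, not raised.

H² = σG² / (σG² + σR²/n) with n the arithmetic mean number of non-missing
replicates per genotype for that trait (the nominal orchard design has 4
trees per genotype but missingness occurs; the harmonic mean would differ
only in strongly unbalanced tables). The genotypic coefficient of variation
is the sample SD of genotypic values (intercept + BLUP) over their mean.

## Multivariate layer

Correlations are reported as signed R² with significance stars at
p ≤ 0.08 / 0.05 / 0.01 / 0.001 (the reporting convention of the orchard
literature this package serves). PCA standardizes traits (correlation-matrix
eigendecomposition — trait units are incommensurable, m³ next to
dimensionless indices) and fixes each axis's sign so its largest-magnitude
loading is positive, for determinism across linear-algebra backends. Ward
clustering runs on the same standardized values (scipy's Ward linkage,
squared-Euclidean increase criterion, Lance–Williams update; scipy's
tie-break is deterministic for a fixed input order) and cuts at k = 6 groups
by default. Group summaries give per-group trait means, a one-way ANOVA p per
trait, and a compact letter display from all pairwise Tukey HSD comparisons
at 0.05 (insert-and-absorb algorithm; letters ordered by descending group
mean). Singleton groups are excluded from Tukey with a warning. Whether to
cluster raw BLUPs, standardized BLUPs or PCA scores is a genuinely open
choice; standardized BLUPs are pinned here because the traits' scales differ
by orders of magnitude.

## Synthetic data: what it emulates, and what it does not

**Crowns** are planar leaf disks (the simplest surrogate with a well-defined
one-sided area, giving an exact STAR denominator TLA = n_leaves · π r²)
placed in an ellipsoidal envelope, optionally displaced into lobes (concave
unions) or clumped around foliage hubs (clumping ∈ [0, 1] contracts leaves
toward sampled hub positions). Points are sampled on each disk.

**Orchards** are rendered on a 5 × 2 m planting grid with alternating
well-watered / water-deficit rows — the standard paired-row trial layout.
Each tree is a circular canopy footprint; vegetation pixels draw from a fixed
leaf spectral signature (NDVI ≈ 0.82) and the tree's true canopy temperature,
soil pixels from a bright-red/low-NIR soil signature (NDVI ≈ 0.09), so the
default NDVI threshold of 0.3 separates the classes cleanly by construction.
A planted per-tree stress level in [0, 1] drives canopy temperature linearly
between −2 and +6 °C relative to air; soil runs +2 to +22 °C. Defaults: 10 cm
pixels, 0.6 m canopy radius, reflectance noise SD 0.01, thermal noise SD
0.5 °C.

**Gas-exchange records** plant per-device coefficients and back-compute Fs
and Fm′ so the fluorescence chain reproduces the planted P_KO/KC exactly.
Campaign defaults mirror a realistic two-device day: 98 + 132 records,
P_KO/KC ∈ (20, 120) µmol m⁻² s⁻¹, T_leaf − T_air ∈ (−2, 8) °C, A_n noise SD
3 µmol m⁻² s⁻¹ — chosen so the planted model implies a calibration R² of
≈ 0.86–0.90, the level reported for well-run IRGA calibrations of this index,
with A_n mostly in the 2–30 µmol m⁻² s⁻¹ range.

**Phenotype tables** follow y = µ + G_i + scenario + (covariates) + e with
G ~ N(0, σG²), e ~ N(0, σR²), and record the implied true H². Defaults match
the core-collection scale: 240 genotypes × 4 replicates.

All generators are bit-reproducible: a single global seed fans out to named
per-stage substreams (SeedSequence keyed by a CRC of the stage name).

What passing tests do **not** show about real data: no radiative-transfer or
illumination effects (the spectral signatures are flat with Gaussian noise),
no mixed soil/vegetation boundary pixels beyond geometric discretization, no
wind-blurred thermal imagery, no leaf angle distributions or woody organs in
the crowns, no genotype × environment interaction, and no missingness
structure. Recovery results on this synthetic material demonstrate the
correctness of the estimators, not the field accuracy of the instruments.

## Pipeline and problem sizes

The demonstration campaign runs 12 genotypes × 4 replicate trees with
350-leaf crowns (5 points per leaf), a 10 cm orchard raster, the two-device
calibration campaign, per-trait mixed models and k = 3 Ward groups — sizes
chosen so the full chain, including repeated-simulation tests, runs
comfortably on a laptop while every stage still has enough data to estimate
its quantities stably. The demo uses α = 0.30 m, matched to the synthetic
cloud density (≈ 2000 points per crown); α = 0.15 corresponds to much denser
terrestrial-LiDAR scans. The heritability-recovery simulations use the full
240-genotype scale. Genotype structure is planted at three levels (log crown
size, stress susceptibility, photosynthetic level) so heritable contrasts
propagate through geometry, imagery and I_PL simultaneously.

Every run writes a `manifest.json` with the config hash, seed, stage list and
the alpha-shape convention; re-running the same config reproduces all output
tables byte for byte. A failing stage halts the pipeline with the stage name,
keeping earlier outputs on disk.

## Known limitations

* The alpha-shape volume uses exact Delaunay tetrahedra rather than the
  curved boundary of the true alpha shape; for dense clouds the difference is
  below the sampling noise.
* The silhouette rasterizer is O(n_points · (r/cell)²) per direction; very
  large clouds should subsample or use the single-zenith option.
* MixedLM fits a single random intercept; spatial row/column effects must be
  supplied as fixed covariates.
* The trapezoid de-bias assumes a roughly uniform fill between the wet and
  dry edges; strongly clustered scatters (e.g. vegetation-only scenes) should
  use manual vertices.
* The compact letter display is the standard insert-and-absorb heuristic; it
  is deterministic but, like all CLDs, not guaranteed minimal in letters.
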