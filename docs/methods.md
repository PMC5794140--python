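# Methods

This note documents the models and procedures implemented in `sepmap`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Classes and codes

Six social-ecological patches (bare soil 1, depression 2, field 3,
forest 4, homestead 5, shrubland 6) plus two plain land covers (water 7,
urban 8); 0 is nodata. Water and urban are mapped but score zero for every
livelihood benefit. Fallow is deliberately not a class: its land cover
ranges from bare-soil-like (young fallow) to shrubland- or
depression-like (old fallow), so it has no stable spectral signature at
30 m and two seasons; its provisioning services are representable as a
mixture of bare soil, field and shrubland.

## Synthetic landscape generator

The generator defines the study conditions for every downstream test.

**Mosaic.** Urban land is one contiguous block around a designated town
(the first village); homesteads are compact clusters around every village
point; water, forest, depression, shrubland and field grow as blobs from
random nuclei by iterative dilation into unclaimed pixels until a pixel
quota is met; the remainder is bare soil. Quotas are the target fractions
times the grid size, so realized composition matches targets up to blob
rounding (tests assert within 0.05). Default composition follows the
published provincial study-area proportions: field 0.50, shrubland 0.29,
depression 0.06, homestead 0.028, forest 0.005, urban 0.005, water 0.002,
remainder bare soil (~0.11). Default grid: 300 × 300 pixels of 30 m in a
projected metric CRS, six villages.

**Vector overlays.** Homestead, depression and urban masks are converted
to polygons by unioning their exact pixel cells, so burning the overlays
back (pixel-center-in-polygon) reproduces the raster mask bit for bit.
This mirrors deposited overlay shapefiles digitized against the same
grid.

**Spectra.** Each pixel draws band reflectance from a per-class,
per-season, per-band Gaussian (clipped to [0, 1]). The default means
encode the qualitative seasonal contrasts the classifier exploits
(rainy-season greening of fields > shrubland > bare soil; forest and
depressions green in both seasons; water dark everywhere; built/bare
surfaces bright in all bands); they are free parameters of the generator,
documented in `examples/config.yaml`, and are *not* calibrated to any
sensor's radiometry. Default noise σ = 0.01 per band keeps all class
pairs above M = 1 on at least one layer — the regime the hybrid method
assumes; σ is the single dial tests use to study degradation, and at
σ = 0.05 the shrubland/field pair drops below M = 1 and tree derivation
correctly refuses with a calibration error.

**DEM.** A Gaussian-smoothed random field (base 300 m, relief σ = 6 m,
smoothing 8 px) minus an 8 m carve under depression polygons, so
depressions coincide with local minima.

**Transects.** Straight walks start within one stop-spacing of a village
point in a random direction, with a stop every 100 m (inclusive
endpoints: `floor(length/spacing) + 1` stops; 3 km default) — 27 walks
give on the order of 800 points, matching a realistic field campaign.
Stops are labeled with the true class at the undisturbed location, then
jittered by isotropic Gaussian GPS noise (default 5 m) and clamped to the
extent. Walks are truncated at the study-area edge with a warning. Roles
are split 50/50 per class into calibration and groundtruth (the split
fraction is configurable). Because transects under-sample rare classes
(water, forest), the pipeline adds a stratified calibration sample of up
to 30 pixel centers per class, emulating calibration digitized from
pre-existing village maps; groundtruthing uses transect points only.

What the generator does **not** emulate: mixed pixels, atmospheric and
illumination effects, spatial autocorrelation of noise, within-class
spectral gradients, topographic shading, clouds. Passing recovery tests
therefore show the pipeline's correctness and its behaviour under
independent pixel noise — not the accuracy attainable on real imagery,
where within-class variance and mixed pixels dominate.

## Derived layers and separability

NDVI is `(NIR − red)/(NIR + red)` with zero-denominator pixels set to
nodata. The tasseled-cap transformation uses the published Landsat 8
at-satellite reflectance coefficients, reduced to the red/NIR/MIR subset
when only those bands are present (the full six-band table ships
alongside and any coefficient set can be substituted; a band without a
coefficient is an error). Class signatures are sample means and n−1
standard deviations of layer values at calibration points
(nearest-pixel lookup; pixel cells are half-open intervals so every
point maps to exactly one pixel); classes with fewer than two points are
skipped with a warning. Separability is
`M = |μ₁ − μ₂| / (σ₁ + σ₂)`; M ≥ 1 is the conventional "good
separability" threshold and the default bar for accepting a tree split.
Zero-variance edge cases: equal means → 0, unequal means → ∞.

## Hybrid classification

Preparatory steps first: vector overlays are burned in order (later
overlays override earlier; a pixel belongs to a polygon if its center is
strictly inside), and overlay pixels are never overwritten by the tree.
Where no overlays exist, a simplified object-based detector thresholds
high-brightness pixels (strict `>`, default the 95th percentile),
extracts 8-connected components, and sorts them by size: within
[min_px, max_px] → homestead candidate; larger and overlapping a village
neighborhood (default 500 m) → urban candidate; others dropped. The
overlay path is authoritative; the detector is a fallback. Depressions
without an overlay are handled by keeping the class in the tree's peeling
order, where the DEM and rainy-season wetness layers separate them.

The tree peels classes in a configurable order (default: water → forest →
depression (when not overlaid) → shrubland → field, with bare soil the
default leaf — biomass-defined classes first, the spectrally weakest
class last). For each class the derivation considers only layers on which
the class mean is extremal relative to the remaining pool — a single
binary threshold cannot isolate a class whose pool straddles it — and
among those picks the layer with the best worst-case M; the threshold is
the midpoint between the class mean and the nearest remaining mean. Ties
at a threshold route to the true branch (comparisons are `<=`/`>=`). If
no eligible layer reaches `m_threshold` the derivation raises a
calibration error naming the class pair, rather than emitting an
unreliable split. Trees serialize to a small YAML mapping and can be
hand-edited and re-loaded; classification is vectorized, total on valid
pixels, and propagates nodata (a pixel nodata in any referenced layer
stays nodata).

## Benefit mapping

The shipped score table encodes qualitative field findings as integers
0–5 per (patch, benefit): every patch supports livestock and hence
saving/insurance (> 0); annual crops come only from fields, depressions
and homestead gardens (zero for bare soil, shrubland, forest); shrubland
and forest lead on material assets & energy and on wild-food nutritional
diversity. The table is a mandatory, swappable config — the defaults are
a documented stand-in, not a claim about any particular community's
scores.

Distance weights: Euclidean distance (on pixel centers, metric CRS
enforced) to the nearest homestead pixel, binned into five 500 m zones;
weights interpolate linearly 1.2 → 0.8 and stay 0.8 beyond the last zone.
The 500 m default makes the five zones span ~2.5 km, a plausible
walking-effort scale for daily management rings; it is config-overridable
and applies around every homestead pixel (not only village centres).
Shrubland-area weights: village territories are Voronoi polygons of the
village points clipped to the extent (duplicate points rejected; cell
areas must sum to the extent area); each territory's shrubland fraction
is binned by breakpoints {0.02, 0.10, 0.25, 0.40} into five categories
with hump-shaped weights {0.8, 1.0, 1.2, 1.1, 0.9} — too little
shrubland cannot sustain use, mid-range is most valuable per unit area,
large surplus is increasingly inaccessible.

A benefit raster is `score(class, benefit) × w_dist × w_area`, where each
weight applies only where the table flags that (class, benefit) pair
(defaults: distance weighting for field and shrubland on all benefits
except saving/insurance; area weighting for shrubland on nutritional
diversity, material assets & energy, and saving/insurance). Where both
flags apply the weights compose multiplicatively. Water, urban and
nodata pixels yield 0 / 0 / NaN. The heat map is the exact per-pixel sum
of the five benefit maps; benefit values are per-unit-area relative
scores and are never normalized for computation.

## Accuracy assessment

A groundtruth point is correct at buffer radius r if the *open* disk of
radius r has positive-area intersection with the *open* cell of at least
one pixel of its true class — equivalently, distance from point to the
closed cell rectangle strictly less than r; touching at an edge or corner
does not count. At r = 0 the measure reduces to plain point-in-pixel
accuracy (handled explicitly), so buffered accuracy is non-decreasing in
r and always ≥ point accuracy — which is why it reads higher than
pixel-to-pixel accuracy. The overall figure is point-pooled; the
unweighted mean of class accuracies is also reported. Urban groundtruth
is excluded from the accuracy table (towns are not surveyed by transect
walks); water is assessed like any patch. The confusion matrix is the
standard point-in-pixel cross-tabulation (rows = predicted,
columns = groundtruth; producer's = recall, user's = precision), and
composition is the percent of valid pixels per class including water and
urban.

## Numerical and I/O choices

Pixel cells are half-open (`[x0 + i·s, x0 + (i+1)·s)`), top edge
inclusive, so point lookup is unambiguous. All randomness flows through
explicit integer seeds via `numpy.random.default_rng`; no global state.
Rasters are TIFFs with grid geometry, CRS tag, nodata and legend stored
as JSON in the ImageDescription tag (integer round-trips are
bit-identical); vectors are GeoJSON; configs YAML; reports JSON + CSV.
CRS handling is a declared-units model (metric vs geographic) with
metric units enforced wherever distances or buffers are computed;
Shapefile reading and full projection support are out of scope.

## Problem sizes

Recovery experiments run on 300 × 300 grids (9 × 9 km at 30 m) with six
villages and 27 transects — large enough that every class is present in
the hundreds-to-tens-of-thousands of pixels and composition targets are
met within tolerance, while a full pipeline run completes in a few
seconds. Oracle-equivalence checks run on 16 × 16 grids where explicit
per-pixel loops are practical.

## Known limitations

- Synthetic spectra are independent Gaussians per pixel; real Landsat
  class distributions are heavier-tailed, spatially correlated and
  season-dependent in ways the generator does not model.
- The derived tree uses one layer per split; the field method also used
  multi-layer node criteria in places.
- The benefit score defaults, zone radii and shrubland breakpoints are
  documented stand-ins for participatory values and should be replaced
  with locally elicited numbers for any real application.
- Voronoi territories approximate village boundaries; actual tenure does
  not follow perpendicular bisectors.
- Regulating and cultural services, fallow mapping, user-group
  disaggregation and multi-scene mosaicking are out of scope.
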