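# Methods

This note documents the models, the numerical choices, what the
synthetic data does and does not emulate, and the design decisions
taken where the underlying workflow left them open.

## Geodesy and projections

All distances use the haversine formula on a sphere of radius
6371.0088 km; at trip scales (≤ 1000 km) the sphere-vs-ellipsoid error
is below 0.5%, far inside every tolerance used here. Metric estimation
(path interpolation, FPT circles, kernel bandwidths and densities) runs
in an azimuthal-equidistant plane centred on the colony or on the data,
where distances from the centre are exact; polygon areas use a Lambert
cylindrical equal-area projection, exact on the sphere. No projection
library is required; both projections are closed-form.

Rasters are exchanged as ESRI ASCII grids (text, six-line georeferenced
header), vectors as GeoJSON, tables as CSV. Grids are regular
longitude/latitude grids, 0.12° cells by default (the coarsest
environmental predictor), with rows stored north-to-south.

## Trips and behaviour

A fix is classed `rest` when the speed of its incoming leg is strictly
below 3 km/h (the conventional threshold separating resting/preening
drift from flight); the first fix inherits the second's label. A trip
is a maximal run of consecutive fixes farther than `buffer_km`
(default 2) from the colony, kept if it lasts ≥ 1 h and has ≥ 5 fixes.
These boundary defaults are conventions, config-exposed, since a
segmentation rule cannot be recovered from reported trip tables. Gaps
over 60 min inside a trip are logged but do not split it (GPS dropout
is routine). Flight time is attributed trapezoidally: each fix carries
half the time gap to each neighbour; this is unbiased for regular
5-min sampling with dropouts. Trips over 3 days (strict) are `long`,
operationalizing the dual-foraging short/long contrast.

## First-passage time and ARS

FPT at a path vertex is the backward first-exit time plus the forward
first-exit time through a circle of radius *r* centred on the vertex —
the standard reading of "time to pass through a circle". Before FPT,
rest bouts are removed and the flight path is reconnected end-to-end
(drift on the water otherwise masquerades as sub-100 m ARS), then the
path is resampled to equal along-path spacing with times interpolated
linearly within each original leg.

Implementation: for each vertex, distances to all other vertices are
computed once; the running maximum of distance along each direction is
monotone, so the first exit segment for every radius is found by binary
search, and the exact segment–circle intersection (larger root of the
quadratic) prorates time within the exit segment. This is O(n²)
per radius set and is validated against a brute-force step-walking
oracle to 1e-9 relative tolerance in the test suite. Vertices whose
circle is never exited before the path ends are undefined and excluded
(not imputed) from the variance.

The two-stage sweep interpolates at 1 km with radii 1–50 km (meso),
then at 0.1 km with radii 0.1–10 km (coarse/small-scale). Var(log FPT)
per radius uses the sample variance over defined vertices; the log
makes the profile invariant to an overall speed rescaling. The detected
scale is the global maximum, accepted only as an interior local
maximum (a boundary maximum means the range did not bracket a peak);
ties break toward the smaller radius. One profile is computed per trip;
whether pooling across trips per bird is preferable is genuinely open —
per-trip keeps trips independent for downstream statistics.

ARS zones are maximal vertex runs with FPT(*r\**) strictly above the
trip's 0.75 quantile of defined values (with a 1e-9 relative epsilon so
numerically uniform straight paths yield no zones); runs closer in time
than one radius at the trip's mean flight speed merge. The quantile is
a convention — no delineation rule can be recovered from an FPT-vs-time
plot description — and is config-exposed. Zones report the time-weighted
centroid, max FPT, entry time, residence (sum of member dwell times)
and colony distance.

## Kernel utilization distributions

Densities are estimated with an isotropic bivariate Gaussian kernel in
the metric plane and reported as density per km² on the geographic
grid, renormalized so that Σ density × cell-area = 1 exactly (cell
areas are exact spherical areas). The LSCV score is evaluated in
closed form from pairwise distances on a 40-point log grid spanning
[0.05, 2] × the Gaussian-reference bandwidth σ·n^(−1/6); a boundary
minimum (the known LSCV failure mode for clumped data) falls back to
the reference bandwidth with a warning. Exact duplicate points are
removed before scoring — they carry no bandwidth information and drive
the score to the lower boundary. One bandwidth is estimated on a
reference dataset and reused across comparison datasets.

Contours accumulate cells by descending density until the enclosed
mass first reaches the level (the standard UD volume convention); the
polygon is the union of the selected cells and may have multiple rings.
VI overlap is Σ min(UD₁, UD₂) × cell-area on a shared grid. Polygon
overlap percentages use the focal-area denominator (overlap area /
focal area × 100) — the denominator convention is stated because
within/among-group overlap tables are ambiguous about it, and reported
within-group SDs exceeding 100 − mean show the original per-pair
denominator is not recoverable.

## Habitat suitability model

The model is the Gibbs/maximum-entropy form: q(x) ∝ exp(λ·f(x)) over
all non-missing grid cells (the background; no thinning), maximizing
the mean presence log-likelihood minus an L1 penalty. Presences are
deduplicated per cell before fitting. Features are linear + quadratic
per predictor after min–max scaling to [0, 1]; product/hinge classes
are excluded for identifiability at these sample sizes. The penalty is
β_j = reg × max(sd_presence(f_j), 0.05)/√m. Optimization is cyclic-free
coordinate descent: each iteration updates the feature with the largest
KKT violation via an exact bounded 1-D search on the concave coordinate
objective, to a 1e-6 gain tolerance; positive gain increments are
attributed to the updated feature's variable, and their normalized sums
are the percent contributions. The logistic output is
p(x) = e^H q(x)/(1 + e^H q(x)) with H the entropy of q, equal to 0.5
where suitability matches the background average.

Evaluation replicates a random 70/30 presence-point split, fits on the
training share, and scores test presences against the full background
with trapezoidal ROC AUC. Held-out points keep their multiplicity
(only training presences are deduplicated): test points are scored as
drawn, which is what makes the measured AUC comparable to the
generating model's. Permutation contribution permutes one raw variable
across the test + background rows and takes the normalized AUC drop.
Jackknife gains (each variable alone / all but one) are computed once
on the full dataset rather than per replicate — 2V + 1 fits instead of
50(2V + 1) — since replicate scatter of training gain is not what the
chart is read for. Qualitative bands: AUC > 0.9 excellent, > 0.8 good,
> 0.7 acceptable, > 0.6 bad, otherwise invalid.

The moving-window gradient layer is
100 × (max − min)/max over each 3 × 3 window, using available cells at
edges, with cells masked where the window maximum is 0 (division
guard). Distance-to-colony is the great-circle distance from each cell
centre. Per-bird balancing subsamples each bird's ARS locations down to
the minimum per-bird count, without replacement, seeded.

## Isotopic niche

The standard ellipse is the 1-SD ellipse (≈ 40% of the mass of a
bivariate normal), SEA = π√det(cov); descriptions of SEAc as a "95%"
ellipse conflict with this standard convention and the standard
convention is implemented. SEAc multiplies by (n−1)/(n−2). SEA_B draws
covariances from the conjugate inverse-Wishart posterior
IW(I + S, (d+1) + n) — a vague, proper, seed-reproducible prior — and
maps each draw to its ellipse area. Group comparison reports
p = mean(area_A < area_B) over paired draws. Ellipse overlap is seeded
Monte-Carlo over the joint bounding box (exact conic intersection is
avoided deliberately; the MC error at 10⁵ points is well under the 1%
reporting tolerance). Layman metrics: per-axis ranges and the convex
hull area; collinear samples get hull area 0 with a warning.

A single experiment's comparison p is nearly uniform under the
symmetric null — the posterior spread of log-area (≈ √(2/n)) matches
the sampling spread of the area estimate — so null calibration is
assessed on the mean of p over hundreds of seeded replicate
experiments, which concentrates at 0.5.

## Synthetic data: what it emulates, and what it does not

Trajectories are correlated random walks at the 5-min fix interval:
gamma step lengths (shape 8, mean = cruise speed × Δt, cruise
30 km/h), von Mises heading increments, goal-biased headings during
colony commutes (blend weight 0.5 toward the target), and near-zero
drift speeds during inserted rest bouts. Inside a patch the cruise
speed is multiplied down (default × 0.55) and the turning concentration
drops (κ = 0.8), producing the elevated residence that FPT detects; a
bird drifting past the patch boundary is steered back at a pace capped
at twice the within-patch speed so small patches are not overshot.
Hierarchical structure — a meso region containing several coarse
sub-patches, with slower, more sinuous search legs between sub-patches
than on commutes — is what creates variance peaks at two scales, as in
the classic FPT simulation literature. Within-patch parameters were
calibrated once, in pilot runs of the generator itself, so that the
*realized* restricted-search extent matches the configured patch
radius (a diffusion-limited walk otherwise under-fills its patch and
the detected scale reports the realized, smaller extent).

Environmental fields are logistic fronts, radial seamount bumps,
constants, or smoothed Gaussian noise; the noise kind can be
rank-Gaussianized so its cell distribution is exactly standard normal.
That matters for the single-driver recovery experiment: with presences
∝ exp(2·z) the presence-vs-background AUC of the generating model is
Φ(√2) ≈ 0.921 when z is standard normal over cells — the exponent
interacts with the field's marginal distribution, and with a [0, 1]
min–max scaled driver no model, including the true one, could exceed
AUC ≈ 0.66 at this effect size. Isotope groups are bivariate normal;
the default means and covariances reproduce the narrow-incubation /
wide-chick-rearing contrast (SEA ≈ 3.4 vs ≈ 18 per-mil²).

What passing these simulations does **not** show: real tracks have
location error, irregular sampling, wind-drift anisotropy and memory
effects; real environmental fields are cross-correlated and
non-stationary; real isotope groups are rarely exactly normal. The
simulations validate the estimators' correctness and calibration, not
their robustness to those field realities.

## Experiment sizes

The validation experiments use 50 seeded trajectories per scale-
recovery condition, 50 evaluation replicates for the habitat models
(60 × 60-cell grids, 300–500 presences), 10⁴ points for UD
calibration, and 300 replicate experiments (n = 150 per group) for the
comparison-p null; at these sizes the Monte-Carlo standard error of
each reported quantity is several times smaller than the acceptance
band it is judged against.

## Known limitations

- FPT is O(n²) per trip; at the 0.1 km stage a 500 km trip (~5000
  vertices) takes a few seconds. Very long multi-week tracks should be
  analysed per trip (as the pipeline does), not concatenated.
- LSCV is unstable for tightly clumped ARS point sets; the reference-
  bandwidth fallback is logged and should be heeded.
- The MaxEnt-analogue omits hinge/product features and background
  thinning; with them, contributions would not be directly comparable
  to the classic software's output at larger sample sizes.
- The equal-area overlap of GeoJSON layers assumes valid, non-self-
  intersecting polygons; no repair is attempted.
- No state-space filtering of raw fixes is provided; input is assumed
  GPS-grade, and Argos-quality data would need pre-filtering.
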