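# foragescape

Analysis toolkit for the at-sea ecology of central-place foraging
seabirds, built around the workflow used to study a tropical shearwater
breeding colony: GPS-track trip segmentation and metrics, two-scale
first-passage-time (FPT) detection of area-restricted search (ARS),
kernel utilization distributions (UD) with contour and overlap
statistics, presence-only maximum-entropy habitat suitability modelling
with a replicate evaluation scheme, and bivariate standard-ellipse
isotopic niche metrics. A seeded synthetic-data module generates every
input with ground truth attached, so the whole chain can be validated
end-to-end without field data.

Intended users are movement and spatial ecologists who want these
analyses as composable, tested Python functions rather than a patchwork
of R scripts.

## The methods in brief

**Trips.** A foraging trip is a maximal run of fixes farther than a
small buffer (default 2 km) from the colony. Fixes arriving at ground
speed < 3 km/h are classed as resting on the water; trips longer than
3 days are "long" (the dual-foraging threshold). Metrics per trip:
duration, total great-circle distance, maximum range, flight h/day.

**FPT / ARS.** The first-passage time at a point of the path is the
time to pass through a circle of radius *r* centred there (backward +
forward first exits). After removing rest bouts and interpolating the
flight path to a fixed step, the analysis runs twice — vertices every
1 km with *r* = 1–50 km, then every 0.1 km with *r* = 0.1–10 km. The
radius maximizing var(log FPT) at each stage is the ARS scale *r\**;
contiguous vertex runs with FPT(*r\**) above the trip's 0.75 quantile
are the ARS zones.

**Space use.** ARS locations feed a bivariate Gaussian kernel UD with
an LSCV bandwidth, estimated in a colony-centred azimuthal-equidistant
km plane and reported on a 0.12° geographic grid. The 50% and 95%
probability contours are the core foraging area (FR) and home range
(HR). UD overlap uses the volume intersection index
VI = ∫ min(UD₁, UD₂); FR-versus-conservation-layer overlap is an
equal-area percentage of the FR.

**Habitat model.** A Gibbs distribution q(x) ∝ exp(λ·f(x)) over the
background cells, with linear + quadratic features of the (min–max
scaled) predictors, fitted by L1-penalized coordinate descent; logistic
output p(x) = e^H q(x)/(1 + e^H q(x)). Evaluation: 50 random 70/30
presence splits, test AUC against the background, mean/CV prediction
maps, percent contribution (gain increments along the optimization
path), permutation contribution (AUC drop), and jackknife gains.

**Isotopic niche.** For (δ¹³C, δ¹⁵N) samples: SEA = π√det(cov) (the
1-SD standard ellipse), SEAc = SEA·(n−1)/(n−2), a seeded
inverse-Wishart posterior for SEA_B, the posterior probability that one
group's area is below another's, Monte-Carlo ellipse overlap, and
Layman range/hull metrics.

## Worked example

```bash
python examples/02_fpt_ars_scales.py
```

prints (seed 3):

```
configured scales: meso 30 km region, coarse 2 km patches
detected meso scale:   32.0 km
detected coarse scale: 2.2 km

  meso zone: centre (-23.249, 16.672), max FPT 25.5 h, residence 4.9 h, 143 km from colony
  ...
```

The bird hopped between seven 2 km prey patches inside a 30 km region
150 km from its colony; the broad FPT sweep recovers the region scale
and the fine sweep the patch scale, each within the simulator's ground
truth. The other examples cover trips (`01`), kernel UDs and overlap
(`03`), the habitat model (`04` — a single driver field yields mean
test AUC ≈ 0.92, the theoretical ceiling for its effect size, with
~100% of both contribution schemes on the true driver), the isotopic
niche contrast (`05`), and the full pipeline (`06`).

The pipeline is also a CLI:

```bash
foragescape run --config run.yaml        # simulate → trips → ars → kud → habitat; isotopes
foragescape trips --tracks tracks.csv --colony -24.5877,16.6113 --out trips/
```

Reruns with identical config and seeds are byte-identical; every stage
writes a manifest with its parameters and input hashes.

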