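"""Seeded generators for every input the pipeline consumes.

The trajectory generator is a correlated random walk (CRW) at the GPS
fix interval (5 min), anchored at a colony: excursions head out to a
prey patch under a persistent, goal-biased heading, forage inside the
patch with reduced speed and increased tortuosity (which is what
produces elevated residence and an FPT variance peak at the patch
scale), optionally dive into a nested smaller patch, and home back to
the colony.  Rest bouts (near-zero drift speed) are inserted at random
so the rest-removal filter has something to remove.  Every generator is
a pure function of (config, seed) and returns its ground truth.

Environmental fields are smooth parametric surfaces (logistic front,
radial seamount bump, constant, or smoothed Gaussian noise) plus seeded
noise; presence points are drawn from a known suitability surface;
isotope groups are bivariate normal with configurable means and
covariances (defaults emulate incubation vs chick-rearing contrasts:
incubation centred at d13C -17.8, d15N 10.2 with a narrow ellipse,
chick-rearing at -19.4, 13.8 with a much wider one).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geo import AzimuthalEquidistant
from .grids import GridSpec, Raster
from .tracks import Trajectory

RASO_COLONY = (-24.5877, 16.6113)  # lon, lat of the breeding islet


@dataclass
class PatchSpec:
    """A circular prey patch in the colony-centred km plane.

    A meso-scale patch may carry ``nested`` coarse-scale sub-patches;
    the bird then hops between the sub-patches (straight legs at cruise
    speed) and forages tortuously inside each, which is the hierarchical
    structure that produces FPT variance peaks at both scales.
    """

    center_km: tuple[float, float]
    radius_km: float
    level: str = "meso"               # {"meso", "coarse"}
    speed_factor: float = 0.55        # within-patch cruise-speed multiplier
    kappa_inside: float = 0.8         # turning concentration inside (low = tortuous)
    forage_h: float = 6.0             # time budgeted inside this patch
    nested: "list[PatchSpec] | None" = None


@dataclass
class TrajectoryConfig:
    """Study conditions for one simulated deployment."""

    seed: int = 0
    individual_id: str = "bird01"
    colony: tuple[float, float] = RASO_COLONY
    fix_interval_min: float = 5.0
    cruise_speed_kmh: float = 30.0
    speed_shape: float = 8.0          # gamma shape of step lengths (cv ~ 0.35)
    kappa_transit: float = 30.0       # heading persistence noise outside patches
    goal_bias: float = 0.5            # weight of the goal bearing during transit
    patches: list[PatchSpec] = field(default_factory=list)
    n_excursions: int = 1
    colony_rest_h: float = 2.0        # time at the colony between excursions
    rest_rate_per_h: float = 0.05     # chance per hour of starting a rest bout
    rest_mean_min: float = 30.0
    rest_speed_kmh: float = 0.5
    max_range_km: float = 1000.0
    start_time: str = "2014-06-01T00:00:00Z"


def _wrap(theta):
    return np.arctan2(np.sin(theta), np.cos(theta))


def _blend_heading(theta, target_bearing, w):
    """Circular convex combination of current heading and a goal bearing."""
    vx = (1 - w) * np.cos(theta) + w * np.cos(target_bearing)
    vy = (1 - w) * np.sin(theta) + w * np.sin(target_bearing)
    return np.arctan2(vy, vx)


class _Walker:
    """Stateful CRW stepper in the colony-centred km plane."""

    def __init__(self, cfg: TrajectoryConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.pos = np.zeros(2)
        self.theta = rng.uniform(-np.pi, np.pi)
        self.dt_h = cfg.fix_interval_min / 60.0
        self.xs: list[float] = [0.0]
        self.ys: list[float] = [0.0]
        self.states: list[str] = ["colony"]
        self.patch_ids: list[int] = [-1]
        self.rest_until = -1

    def step(self, speed_kmh, kappa, target=None, bias=0.0, state="transit",
             patch_id=-1):
        cfg, rng = self.cfg, self.rng
        i = len(self.xs)
        if i <= self.rest_until:
            speed_kmh, kappa, bias = cfg.rest_speed_kmh, 0.1, 0.0
            state = "rest"
        elif state == "forage" and rng.random() < cfg.rest_rate_per_h * self.dt_h:
            n_rest = max(1, int(rng.exponential(cfg.rest_mean_min)
                                / cfg.fix_interval_min))
            self.rest_until = i + n_rest - 1
            speed_kmh, kappa, bias = cfg.rest_speed_kmh, 0.1, 0.0
            state = "rest"
        if target is not None and bias > 0:
            bearing = np.arctan2(target[1] - self.pos[1], target[0] - self.pos[0])
            self.theta = _blend_heading(self.theta, bearing, bias)
        self.theta = _wrap(self.theta + rng.vonmises(0.0, kappa))
        mean_step = speed_kmh * self.dt_h
        step = rng.gamma(cfg.speed_shape, mean_step / cfg.speed_shape)
        self.pos = self.pos + step * np.array([np.cos(self.theta),
                                               np.sin(self.theta)])
        self.xs.append(float(self.pos[0]))
        self.ys.append(float(self.pos[1]))
        self.states.append(state)
        self.patch_ids.append(patch_id)


def _forage_in_patch(w: _Walker, patch: PatchSpec, patch_id: int,
                     hours: float, kappa_override=None, speed_override=None):
    """Tortuous slow CRW confined to the patch.

    Within-patch speed and turning are set by the patch spec (slower
    and much more tortuous than transit); a bird that drifts past the
    boundary is steered back toward the centre, so the realized
    restricted-search extent tracks the configured radius.
    """
    cfg = w.cfg
    n_steps = int(round(hours / w.dt_h))
    speed = speed_override if speed_override is not None else \
        cfg.cruise_speed_kmh * patch.speed_factor
    kappa = kappa_override if kappa_override is not None else patch.kappa_inside
    center = np.asarray(patch.center_km)
    for _ in range(n_steps):
        d = np.linalg.norm(w.pos - center)
        if d > patch.radius_km:
            # drifted out: head back in, at a pace that cannot overshoot a
            # small patch in a single step
            re_speed = min(cfg.cruise_speed_kmh * 0.8, 2.0 * speed)
            w.step(re_speed, cfg.kappa_transit, target=center,
                   bias=0.8, state="forage", patch_id=patch_id)
        else:
            w.step(speed, kappa, state="forage", patch_id=patch_id)


def _transit_to(w: _Walker, target, arrive_km: float, state: str,
                patch_id: int = -1, max_steps: int = 20000,
                speed_kmh: float | None = None, kappa: float | None = None,
                bias: float | None = None):
    cfg = w.cfg
    target = np.asarray(target, dtype=float)
    for _ in range(max_steps):
        if np.linalg.norm(w.pos - target) <= arrive_km:
            return
        w.step(speed_kmh if speed_kmh is not None else cfg.cruise_speed_kmh,
               kappa if kappa is not None else cfg.kappa_transit,
               target=target,
               bias=bias if bias is not None else cfg.goal_bias,
               state=state, patch_id=patch_id)
    raise RuntimeError("transit failed to reach its target")


def simulate_trajectory(config: TrajectoryConfig) -> tuple[Trajectory, dict]:
    """Simulate one deployment; returns the Trajectory and its ground truth.

    Ground truth records, per fix, the behavioural state, the patch the
    bird was foraging in (index into ``config.patches``, -1 outside),
    and the excursion index (-1 at the colony); plus the configured
    patch geometry and excursion count.
    """
    cfg = config
    for p in cfg.patches:
        if np.linalg.norm(p.center_km) > cfg.max_range_km:
            raise ValueError(
                f"patch at {p.center_km} exceeds max range {cfg.max_range_km} km")
    rng = np.random.default_rng(cfg.seed)
    w = _Walker(cfg, rng)
    excursion_of_fix = [-1]
    n_colony_steps = max(1, int(round(cfg.colony_rest_h / w.dt_h)))
    for exc in range(cfg.n_excursions):
        start_len = len(w.xs)
        for pid, patch in enumerate(cfg.patches):
            _transit_to(w, patch.center_km, arrive_km=0.6 * patch.radius_km,
                        state="outbound")
            if patch.nested:
                step_km = cfg.cruise_speed_kmh * w.dt_h
                for sub in patch.nested:
                    # searching between sub-patches is slower and more sinuous
                    # than colony commuting: the meso region itself is an
                    # area of restricted search
                    _transit_to(w, sub.center_km,
                                arrive_km=max(0.5 * sub.radius_km, 1.1 * step_km),
                                state="search", patch_id=pid,
                                speed_kmh=0.75 * cfg.cruise_speed_kmh,
                                kappa=4.0, bias=0.35)
                    _forage_in_patch(w, sub, pid, sub.forage_h)
            else:
                _forage_in_patch(w, patch, pid, patch.forage_h)
        # arrival radius of order one step length: the bird "lands" as soon
        # as a step brings it within the colony buffer
        arrive = max(2.0, 0.9 * cfg.cruise_speed_kmh * w.dt_h)
        _transit_to(w, (0.0, 0.0), arrive_km=arrive, state="homing")
        excursion_of_fix.extend([exc] * (len(w.xs) - start_len))
        # settle at the colony between excursions
        at_colony_start = len(w.xs)
        for _ in range(n_colony_steps):
            w.pos = w.pos * 0.0
            w.xs.append(0.0)
            w.ys.append(0.0)
            w.states.append("colony")
            w.patch_ids.append(-1)
        excursion_of_fix.extend([-1] * (len(w.xs) - at_colony_start))

    n = len(w.xs)
    proj = AzimuthalEquidistant(*cfg.colony)
    lon, lat = proj.inverse(np.array(w.xs), np.array(w.ys))
    t0 = pd.Timestamp(cfg.start_time)
    times = t0 + pd.to_timedelta(np.arange(n) * cfg.fix_interval_min, unit="m")
    fixes = pd.DataFrame({"timestamp": times, "lon": lon, "lat": lat})
    traj = Trajectory(individual_id=cfg.individual_id, colony=cfg.colony,
                      fixes=fixes)
    truth = {
        "individual_id": cfg.individual_id,
        "n_excursions": cfg.n_excursions,
        "excursion_of_fix": excursion_of_fix,
        "state_of_fix": w.states,
        "patch_of_fix": w.patch_ids,
        "patches": [
            {"center_km": list(p.center_km), "radius_km": p.radius_km,
             "level": p.level,
             "nested": [{"center_km": list(s.center_km),
                         "radius_km": s.radius_km, "level": s.level}
                        for s in (p.nested or [])]}
            for p in cfg.patches
        ],
    }
    return traj, truth


# ---------------------------------------------------------------------------
# environmental fields

def simulate_raster(grid: GridSpec, kind: str, params: dict | None = None,
                    seed: int = 0, name: str | None = None) -> Raster:
    """Seeded synthetic environmental field on a geographic grid.

    Kinds: ``uniform`` (constant), ``front`` (logistic step across a
    lon or lat line; its window gradient is maximal along the front),
    ``seamount`` (radial Gaussian bump), ``noise`` (smoothed Gaussian
    noise standardized to mean 0, sd 1 across cells).  All kinds accept
    ``noise_sd`` for additive white noise.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    lon_m, lat_m = grid.center_mesh()
    if kind == "uniform":
        vals = np.full(lon_m.shape, float(params.get("value", 1.0)))
    elif kind == "front":
        axis = params.get("axis", "lon")
        coord = lon_m if axis == "lon" else lat_m
        pos = float(params.get("position",
                               coord.min() + 0.5 * (coord.max() - coord.min())))
        width = float(params.get("width_deg", 0.3))
        lo, hi = float(params.get("low", 18.0)), float(params.get("high", 26.0))
        vals = lo + (hi - lo) / (1.0 + np.exp(-(coord - pos) / width))
    elif kind == "seamount":
        c = params.get("center", (float(lon_m.mean()), float(lat_m.mean())))
        s = float(params.get("sigma_deg", 0.5))
        base = float(params.get("base", -4000.0))
        amp = float(params.get("amplitude", 3500.0))
        d2 = (lon_m - c[0]) ** 2 + (lat_m - c[1]) ** 2
        vals = base + amp * np.exp(-d2 / (2.0 * s * s))
    elif kind == "noise":
        sigma_cells = float(params.get("sigma_cells", 3.0))
        vals = gaussian_filter(rng.standard_normal(lon_m.shape), sigma_cells,
                               mode="wrap")
        if params.get("gaussianize", False):
            # rank-based inverse-normal transform: the cell distribution
            # becomes exactly standard normal while the spatial pattern
            # (rank order) is preserved
            from scipy.stats import norm
            flat = vals.ravel()
            ranks = np.argsort(np.argsort(flat))
            vals = norm.ppf((ranks + 0.5) / len(flat)).reshape(vals.shape)
        else:
            vals = (vals - vals.mean()) / vals.std()
    else:
        raise ValueError(f"unknown raster kind {kind!r}")
    noise_sd = float(params.get("noise_sd", 0.0))
    if noise_sd > 0:
        vals = vals + noise_sd * rng.standard_normal(vals.shape)
    return Raster(name=name or kind.upper(), grid=grid, values=vals)


def simulate_presences(suitability: Raster, n: int, seed: int = 0):
    """Draw n presence points with probability proportional to suitability.

    Cells are sampled multinomially; each point is jittered uniformly
    within its cell.  Returns (points (n, 2) lon/lat, ground truth with
    the drawn cell indices).
    """
    w = np.asarray(suitability.values, dtype=float).copy()
    w[~np.isfinite(w)] = 0.0
    if (w < 0).any():
        raise ValueError("suitability must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate suitability: all zero")
    rng = np.random.default_rng(seed)
    flat_p = (w / total).ravel()
    cells = rng.choice(len(flat_p), size=int(n), p=flat_p)
    rows, cols = np.unravel_index(cells, w.shape)
    g = suitability.grid
    lon = g.xll + (cols + rng.uniform(0, 1, size=len(cells))) * g.cell_deg
    lat_s = g.nrows - 1 - rows  # south-up index
    lat = g.yll + (lat_s + rng.uniform(0, 1, size=len(cells))) * g.cell_deg
    pts = np.column_stack([lon, lat])
    return pts, {"cells": cells.tolist(), "n": int(n)}


# ---------------------------------------------------------------------------
# isotope samples

DEFAULT_ISOTOPE_GROUPS = {
    # means from incubation vs chick-rearing whole-blood signatures;
    # covariances chosen so SEA matches the narrow (~3.4) and wide
    # (~18.1 per-mil^2) niches of the two phases
    "incubation": {"mean": (-17.8, 10.2), "cov": [[0.36, 0.0], [0.0, 3.24]]},
    "chick_rearing": {"mean": (-19.4, 13.8), "cov": [[4.0, 0.0], [0.0, 8.2944]]},
}


def simulate_isotopes(groups: dict | None = None, n_per_group: int = 22,
                      seed: int = 0):
    """Bivariate-normal isotope samples per group.

    ``groups`` maps a group label to {"mean": (d13C, d15N), "cov": 2x2}.
    Returns (DataFrame with columns individual_id, group, d13C, d15N;
    ground-truth dict echoing the generating parameters).
    """
    groups = groups or DEFAULT_ISOTOPE_GROUPS
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for gname in sorted(groups):
        spec = groups[gname]
        mean = np.asarray(spec["mean"], dtype=float)
        cov = np.asarray(spec["cov"], dtype=float)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(f"group {gname!r}: covariance not positive definite")
        n = int(spec.get("n", n_per_group))
        draws = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
        for i, (c, nn) in enumerate(draws):
            rows.append({"individual_id": f"{gname}_{i + 1:03d}", "group": gname,
                         "d13C": c, "d15N": nn})
        truth[gname] = {"mean": mean.tolist(), "cov": cov.tolist(), "n": n}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# canonical study presets

def single_patch_config(seed: int, patch_radius_km: float = 10.0,
                        patch_dist_km: float = 60.0,
                        n_excursions: int = 3) -> TrajectoryConfig:
    """Excursions to a single meso-scale patch (scale-recovery conditions).

    Several excursions per deployment give several trips, whose
    per-trip detected scales can be summarized (median) at the
    trajectory level.
    """
    patch = PatchSpec(center_km=(patch_dist_km, 0.0), radius_km=patch_radius_km,
                      level="meso", forage_h=6.0)
    return TrajectoryConfig(seed=seed, patches=[patch],
                            n_excursions=n_excursions)


def nested_patch_config(seed: int, meso_radius_km: float = 30.0,
                        coarse_radius_km: float = 2.0,
                        patch_dist_km: float = 150.0,
                        n_sub: int = 7) -> TrajectoryConfig:
    """One excursion to a meso region holding several nested coarse patches.

    The sub-patch layout (uniform in the inner 60% of the meso disc) is
    a deterministic function of the seed; the bird hops between
    sub-patches with sinuous search legs and forages slowly inside
    each, so the FPT variance peaks near the coarse radius at the fine
    stage and near the meso radius at the broad stage.
    """
    layout_rng = np.random.default_rng(seed + 77003)
    subs = []
    for _ in range(n_sub):
        r = 0.6 * meso_radius_km * np.sqrt(layout_rng.random())
        a = layout_rng.uniform(-np.pi, np.pi)
        subs.append(PatchSpec(
            center_km=(patch_dist_km + r * np.cos(a), r * np.sin(a)),
            radius_km=coarse_radius_km, level="coarse",
            speed_factor=0.22, kappa_inside=0.3, forage_h=1.5))
    meso = PatchSpec(center_km=(patch_dist_km, 0.0), radius_km=meso_radius_km,
                     level="meso", forage_h=9.0, nested=subs)
    return TrajectoryConfig(seed=seed, patches=[meso], n_excursions=1)
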