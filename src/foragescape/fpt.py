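"""First-passage time (FPT) analysis and area-restricted-search detection.

FPT at a point of a path is the time the animal takes to pass through a
circle of radius *r* centred there: the first-exit time moving forward
along the path plus the first-exit time moving backward.  Sliding the
circle along the whole path and varying *r* gives a scale-dependent
measure of search effort; the radius maximizing the variance of
log(FPT) is the characteristic scale of area-restricted search (ARS).

The analysis runs in two stages on each trip: a coarse sweep (vertices
every 1 km, radii 1-50 km) for meso-scale ARS, and a fine sweep
(vertices every 0.1 km, radii 0.1-10 km) for small-scale events.  Rest
bouts on the water are removed before interpolation so that drift noise
does not masquerade as small-scale ARS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import AzimuthalEquidistant, great_circle_km
from .tracks import Trip

MESO_STEP_KM = 1.0
MESO_RADII_KM = np.arange(1, 51, dtype=float)          # 1..50 km, 50 radii
COARSE_STEP_KM = 0.1
COARSE_RADII_KM = np.arange(1, 101, dtype=float) / 10  # 0.1..10 km, 100 radii
ZONE_QUANTILE = 0.75


@dataclass
class InterpolatedPath:
    """Flight path resampled to equal along-path spacing, in a local km plane."""

    xy: np.ndarray            # (n, 2) km, azimuthal-equidistant plane
    t_h: np.ndarray           # hours since first vertex, non-decreasing
    t0: pd.Timestamp          # absolute time of the first vertex
    step_km: float
    proj: AzimuthalEquidistant
    colony: tuple[float, float]

    @property
    def n_vertices(self) -> int:
        return len(self.xy)

    @property
    def length_km(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.xy, axis=0).T)))

    def lonlat(self):
        return self.proj.inverse(self.xy[:, 0], self.xy[:, 1])


@dataclass
class FptProfile:
    """Per-vertex FPT across radii and the variance-of-log profile."""

    radii: np.ndarray         # (R,) km
    fpt: np.ndarray           # (n, R) hours; NaN where undefined
    var_log_fpt: np.ndarray   # (R,) sample variance of ln FPT; NaN if < 2 defined
    n_defined: np.ndarray     # (R,) count of defined vertices


@dataclass
class ArsZone:
    """A contiguous high-FPT stretch of the path at the detected scale."""

    scale_km: float
    center_lon: float
    center_lat: float
    max_fpt_h: float
    entry_time: pd.Timestamp
    residence_h: float
    dist_colony_km: float
    vertex_start: int
    vertex_stop: int          # exclusive


def interpolate_path(trip: Trip, step_km: float,
                     colony: tuple[float, float] | None = None) -> InterpolatedPath:
    """Remove rest bouts, reconnect, and resample the flight path.

    Vertices are equally spaced (``step_km``) along the rectified path
    (the final segment may be shorter so endpoints are preserved
    exactly); vertex times are linearly interpolated within each
    original leg.
    """
    f = trip.fixes
    if "behaviour" not in f.columns:
        raise ValueError("trip must be behaviour-labelled before interpolation")
    flight = f[f["behaviour"] == "flight"]
    if len(flight) < 2:
        raise ValueError(
            f"trip {trip.trip_id}: fewer than 2 flight fixes, cannot interpolate")
    colony = colony or trip.colony
    proj = AzimuthalEquidistant(*colony)
    x, y = proj.forward(flight["lon"].to_numpy(), flight["lat"].to_numpy())
    t = flight["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64") / 3.6e12
    t0 = flight["timestamp"].iloc[0]
    t = t - t[0]
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = s[-1]
    if length <= 0:
        raise ValueError(f"trip {trip.trip_id}: rectified path has zero length")
    n_steps = int(np.floor(length / step_km + 1e-9))
    s_new = np.arange(n_steps + 1) * step_km
    if length - s_new[-1] > 1e-6 * step_km:
        s_new = np.append(s_new, length)
    else:
        s_new[-1] = length  # absorb float fuzz; endpoint is exact
    # strictly increasing abscissa needed for interp when legs have zero length
    keep = np.concatenate([[True], np.diff(s) > 0])
    xi = np.interp(s_new, s[keep], x[keep])
    yi = np.interp(s_new, s[keep], y[keep])
    ti = np.interp(s_new, s[keep], t[keep])
    return InterpolatedPath(xy=np.column_stack([xi, yi]), t_h=ti, t0=t0,
                            step_km=step_km, proj=proj, colony=tuple(colony))


def _exit_times(xy: np.ndarray, d: np.ndarray, t: np.ndarray,
                radii: np.ndarray) -> np.ndarray:
    """First-exit times (hours) from circles of each radius, one direction.

    ``xy`` are vertices ordered away from the circle centre ``xy[0]``,
    ``d`` their distances from the centre, ``t`` elapsed hours from the
    centre vertex.  Exit is located by exact segment-circle
    intersection with linear proration of time inside the exit segment.
    Radii must be sorted ascending.  NaN where the path ends first.
    """
    out = np.full(len(radii), np.nan)
    m = np.maximum.accumulate(d)
    idx = np.searchsorted(m, radii, side="right")
    valid = idx < len(d)
    if not valid.any():
        return out
    j = idx[valid]
    r = radii[valid]
    p0 = xy[j - 1] - xy[0]
    p1 = xy[j] - xy[0]
    dv = p1 - p0
    a = np.einsum("ij,ij->i", dv, dv)
    b = 2.0 * np.einsum("ij,ij->i", p0, dv)
    c = np.einsum("ij,ij->i", p0, p0) - r * r
    disc = np.maximum(b * b - 4.0 * a * c, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(a > 1e-300, (-b + np.sqrt(disc)) / (2.0 * a), 1.0)
    frac = np.clip(frac, 0.0, 1.0)
    out[valid] = t[j - 1] + frac * (t[j] - t[j - 1])
    return out


def first_passage_time(path: InterpolatedPath, radii) -> np.ndarray:
    """FPT (hours) for every vertex at each radius.

    Returns shape ``(n_vertices, n_radii)`` (or ``(n_vertices,)`` for a
    scalar radius).  A vertex is undefined (NaN) for a radius whenever
    the path ends before exiting the circle in either direction.
    """
    scalar = np.isscalar(radii)
    radii_arr = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii_arr <= 0):
        raise ValueError("radii must be positive")
    if np.any(np.diff(radii_arr) < 0):
        raise ValueError("radii must be sorted ascending")
    xy, t = path.xy, path.t_h
    n = len(xy)
    fpt = np.full((n, len(radii_arr)), np.nan)
    for i in range(n):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        fwd = _exit_times(xy[i:], d[i:], t[i:] - t[i], radii_arr)
        bwd = _exit_times(xy[i::-1], d[i::-1], t[i] - t[i::-1], radii_arr)
        fpt[i] = fwd + bwd
    return fpt[:, 0] if scalar else fpt


def variance_profile(path: InterpolatedPath, radii) -> FptProfile:
    """Variance of log(FPT) across vertices, per radius.

    FPT is log-transformed so the variance is independent of the
    magnitude of the mean; undefined vertices are excluded (not
    imputed).  Radii with fewer than 2 defined vertices get NaN.
    """
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    fpt = first_passage_time(path, radii)
    with np.errstate(invalid="ignore", divide="ignore"):
        logf = np.log(fpt)
    logf[~np.isfinite(logf)] = np.nan
    n_def = np.sum(np.isfinite(logf), axis=0)
    var = np.full(len(radii), np.nan)
    ok = n_def >= 2
    if ok.any():
        col = logf[:, ok]
        mean = np.nanmean(col, axis=0)
        var[ok] = np.nansum((col - mean) ** 2, axis=0) / (n_def[ok] - 1)
    return FptProfile(radii=radii, fpt=fpt, var_log_fpt=var, n_defined=n_def)


def detect_ars_scale(profile: FptProfile) -> float | None:
    """Radius of the global variance peak, if it is an interior maximum.

    Ties break toward the smaller radius.  Returns None when fewer than
    3 radii are defined or when the maximum sits on the boundary of the
    defined range (no resolvable peak).
    """
    vl = profile.var_log_fpt
    finite = np.flatnonzero(np.isfinite(vl))
    if len(finite) < 3:
        return None
    sub = vl[finite]
    k = int(np.argmax(sub))  # first occurrence -> smaller radius on ties
    if k == 0 or k == len(finite) - 1:
        return None
    return float(profile.radii[finite[k]])


def delineate_ars_zones(path: InterpolatedPath, r_star: float,
                        q: float = ZONE_QUANTILE,
                        fpt_at_scale: np.ndarray | None = None) -> list[ArsZone]:
    """Cut ARS zones from the FPT-versus-time profile at the detected scale.

    Zones are maximal runs of vertices whose FPT at ``r_star`` exceeds
    the trip's ``q``-quantile of defined FPT values; runs closer in time
    than the time to fly one radius at the trip's mean flight speed are
    merged.  Zones are returned in entry-time order.
    """
    if fpt_at_scale is None:
        fpt_at_scale = first_passage_time(path, float(r_star))
    fpt = np.asarray(fpt_at_scale, dtype=float)
    defined = np.isfinite(fpt)
    if defined.sum() == 0:
        return []
    thr = np.nanquantile(fpt[defined], q)
    # strictly above, with a relative epsilon so numerically-uniform paths
    # (e.g. straight constant-speed transit) yield no spurious zones
    above = defined & (fpt > thr + 1e-9 * max(abs(thr), 1.0))
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(int), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))
    total_t = path.t_h[-1] - path.t_h[0]
    mean_speed = path.length_km / total_t if total_t > 0 else np.inf
    merge_gap_h = r_star / mean_speed if np.isfinite(mean_speed) and mean_speed > 0 else 0.0
    merged = [list(runs[0])]
    for i0, i1 in runs[1:]:
        if path.t_h[i0] - path.t_h[merged[-1][1] - 1] < merge_gap_h:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    # dwell time per vertex for time-weighted centroids
    dwell = np.zeros(len(path.t_h))
    gaps = np.diff(path.t_h)
    dwell[:-1] += gaps / 2.0
    dwell[1:] += gaps / 2.0
    zones = []
    for i0, i1 in merged:
        idx = np.arange(i0, i1)
        w = dwell[idx]
        w = w / w.sum() if w.sum() > 0 else np.full(len(idx), 1.0 / len(idx))
        cx = float(np.sum(path.xy[idx, 0] * w))
        cy = float(np.sum(path.xy[idx, 1] * w))
        lon, lat = path.proj.inverse(cx, cy)
        residence = float(dwell[idx].sum())
        zones.append(ArsZone(
            scale_km=float(r_star),
            center_lon=float(lon), center_lat=float(lat),
            max_fpt_h=float(np.nanmax(fpt[idx])),
            entry_time=path.t0 + pd.to_timedelta(path.t_h[i0], unit="h"),
            residence_h=residence,
            dist_colony_km=float(great_circle_km(lon, lat, *path.colony)),
            vertex_start=int(i0), vertex_stop=int(i1)))
    return zones


@dataclass
class StageResult:
    """One FPT stage: its sweep, the detected scale and the zones."""

    step_km: float
    profile: FptProfile | None
    scale_km: float | None
    zones: list[ArsZone] = field(default_factory=list)


@dataclass
class TwoStageResult:
    meso: StageResult
    coarse: StageResult


def _run_stage(trip: Trip, step_km: float, radii: np.ndarray,
               q: float) -> StageResult:
    try:
        path = interpolate_path(trip, step_km)
    except ValueError:
        return StageResult(step_km=step_km, profile=None, scale_km=None)
    profile = variance_profile(path, radii)
    scale = detect_ars_scale(profile)
    zones: list[ArsZone] = []
    if scale is not None:
        col = int(np.argmin(np.abs(profile.radii - scale)))
        zones = delineate_ars_zones(path, scale, q=q,
                                    fpt_at_scale=profile.fpt[:, col])
    return StageResult(step_km=step_km, profile=profile, scale_km=scale,
                       zones=zones)


def two_stage_ars(trip: Trip, q: float = ZONE_QUANTILE) -> TwoStageResult:
    """Run the two-step FPT scheme on one trip.

    Stage 1 (meso): vertices every 1 km, radii 1-50 km in 1 km steps.
    Stage 2 (coarse, i.e. small-scale): vertices every 0.1 km, radii
    0.1-10 km in 0.1 km steps.  Each stage reports its own variance
    profile, scale and zones; a stage that cannot resolve a peak (e.g.
    a trip shorter than the radii probed) reports scale None.
    """
    meso = _run_stage(trip, MESO_STEP_KM, MESO_RADII_KM, q)
    coarse = _run_stage(trip, COARSE_STEP_KM, COARSE_RADII_KM, q)
    return TwoStageResult(meso=meso, coarse=coarse)
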