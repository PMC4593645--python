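"""Presence-only maximum-entropy habitat suitability modelling.

The model is a Gibbs distribution q(x) proportional to exp(lambda . f(x))
over the background cells of the study grid, with features f built from
the environmental predictors (each min-max scaled to [0, 1], with linear
and quadratic classes), fitted by maximizing the L1-regularized mean
presence log-likelihood with coordinate descent.  The logistic output
p(x) = e^H q(x) / (1 + e^H q(x)) (H = entropy of q) rescales the raw
density to (0, 1), equal to 0.5 where suitability matches the background
average.

Evaluation mirrors the standard presence-only protocol: replicate
random 70/30 presence splits, test AUC against the full background,
mean and coefficient-of-variation prediction maps, percent contribution
(positive training-gain increments along the coordinate-descent path,
per variable), permutation contribution (AUC drop after permuting one
variable), and jackknife gains (each variable alone / all but one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

from .geo import great_circle_km
from .grids import GridSpec, Raster

logger = logging.getLogger(__name__)

AUC_CATEGORIES = (  # qualitative bands for mean test AUC
    (0.90, "excellent"), (0.80, "good"), (0.70, "acceptable"),
    (0.60, "bad"), (0.50, "invalid"),
)


# ---------------------------------------------------------------------------
# predictor-layer operations

def window_gradient(raster: Raster, suffix: str = "G") -> Raster:
    """Rate-of-change layer: 100 x (max - min) / max over each 3x3 window.

    Edge and corner cells use only their in-bounds neighbours; missing
    neighbours are ignored.  Cells whose window maximum is 0 are set
    missing (division guard).
    """
    v = raster.values
    padded = np.full((v.shape[0] + 2, v.shape[1] + 2), np.nan)
    padded[1:-1, 1:-1] = v
    stack = np.stack([padded[r:r + v.shape[0], c:c + v.shape[1]]
                      for r in range(3) for c in range(3)])
    with np.errstate(all="ignore"):
        wmax = np.nanmax(stack, axis=0)
        wmin = np.nanmin(stack, axis=0)
        grad = (wmax - wmin) * 100.0 / wmax
    grad[~np.isfinite(grad)] = np.nan
    grad[wmax == 0] = np.nan
    return raster.copy_with(grad, name=raster.name + suffix)


def distance_to_colony(grid: GridSpec, colony: tuple[float, float],
                       name: str = "DCOL") -> Raster:
    """Great-circle distance (km) from every cell centre to the colony."""
    lon_m, lat_m = grid.center_mesh()
    d = great_circle_km(lon_m, lat_m, colony[0], colony[1])
    return Raster(name=name, grid=grid, values=d, units="km")


def balanced_subsample(zones_by_bird: dict, seed: int) -> list:
    """Equalize per-bird sample sizes by seeded subsampling.

    Draws ``n = min`` per-bird count without replacement from each
    bird's list, so no individual dominates the model.  Deterministic
    given the seed; returns the selected items concatenated in sorted
    bird order.
    """
    if not zones_by_bird or any(len(v) == 0 for v in zones_by_bird.values()):
        raise ValueError("every bird must contribute at least one location")
    n = min(len(v) for v in zones_by_bird.values())
    rng = np.random.default_rng(seed)
    out = []
    for bird in sorted(zones_by_bird, key=str):
        items = list(zones_by_bird[bird])
        idx = rng.choice(len(items), size=n, replace=False)
        out.extend(items[i] for i in sorted(idx))
    return out


# ---------------------------------------------------------------------------
# model fitting

def _check_stack(rasters: list[Raster]) -> GridSpec:
    grid = rasters[0].grid
    for r in rasters[1:]:
        if not r.grid.same_as(grid):
            raise ValueError(f"raster {r.name!r} is not on the shared grid")
    return grid


def _design(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Feature matrix: per variable, min-max scaled linear + quadratic."""
    rng_ = np.where(hi > lo, hi - lo, 1.0)
    z = np.clip((X - lo) / rng_, 0.0, 1.0)
    nvar = X.shape[1]
    F = np.empty((X.shape[0], 2 * nvar))
    F[:, 0::2] = z
    F[:, 1::2] = z * z
    return F


@dataclass
class HabitatModel:
    """Fitted maximum-entropy suitability model."""

    var_names: list[str]
    lambdas: np.ndarray          # (2V,) feature weights
    beta: np.ndarray             # (2V,) L1 penalty per feature
    scale_lo: np.ndarray         # (V,) per-variable min over background
    scale_hi: np.ndarray
    grid: GridSpec
    bg_flat_index: np.ndarray    # flat cell indices of background cells
    bg_X: np.ndarray             # (N, V) raw predictor values, background
    presence_cells: np.ndarray   # flat indices of (deduplicated) presence cells
    entropy: float               # H of the fitted distribution
    gain: float                  # regularized training gain over uniform
    gain_increments: dict = field(default_factory=dict)  # var -> summed +gain
    reg: float = 1.0

    @property
    def feature_names(self) -> list[str]:
        return [f"{v}:{k}" for v in self.var_names for k in ("linear", "quadratic")]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return _design(X, self.scale_lo, self.scale_hi) @ self.lambdas

    def raw_density(self, X: np.ndarray) -> np.ndarray:
        """q(x), normalized over the model's training background."""
        eta_bg = self.linear_predictor(self.bg_X)
        log_z = logsumexp(eta_bg)
        return np.exp(self.linear_predictor(X) - log_z)

    def logistic(self, X: np.ndarray) -> np.ndarray:
        """Logistic output in (0, 1); 0.5 at background-average suitability."""
        q = self.raw_density(X)
        eq = np.exp(self.entropy) * q
        return eq / (1.0 + eq)

    def predict_raster(self, rasters: list[Raster], name: str = "suitability") -> Raster:
        grid = _check_stack(rasters)
        X = np.column_stack([r.values.ravel() for r in rasters])
        ok = np.all(np.isfinite(X), axis=1)
        out = np.full(X.shape[0], np.nan)
        out[ok] = self.logistic(X[ok])
        return Raster(name=name, grid=grid, values=out.reshape(grid.nrows, grid.ncols))


def _coordinate_descent(F_bg, p_mean, beta, tol=1e-6, max_iter=1000):
    """L1-penalized MaxEnt fit; returns (lambdas, gain, per-feature +increments).

    Gain is the penalized mean presence log-likelihood relative to the
    uniform distribution.  Each iteration updates the single feature
    with the largest optimality violation via an exact 1-D concave
    line search.
    """
    n_feat = F_bg.shape[1]
    lam = np.zeros(n_feat)
    eta = np.zeros(F_bg.shape[0])
    increments = np.zeros(n_feat)

    def penalized_gain(lam_, eta_):
        return float(lam_ @ p_mean - (logsumexp(eta_) - np.log(len(eta_)))
                     - np.sum(beta * np.abs(lam_)))

    gain = 0.0
    for _ in range(max_iter):
        w = np.exp(eta - eta.max())
        q = w / w.sum()
        q_mean = q @ F_bg
        grad = p_mean - q_mean
        viol = np.where(lam == 0.0,
                        np.maximum(np.abs(grad) - beta, 0.0),
                        np.abs(grad - beta * np.sign(lam)))
        j = int(np.argmax(viol))
        if viol[j] < tol:
            break
        f = F_bg[:, j]

        def neg_delta(d, f=f, j=j):
            # change in penalized gain for lam_j -> lam_j + d (concave in d)
            return -(d * p_mean[j] - (logsumexp(eta + d * f) - logsumexp(eta))
                     - beta[j] * (abs(lam[j] + d) - abs(lam[j])))

        res = minimize_scalar(neg_delta, bounds=(-8.0, 8.0), method="bounded",
                              options={"xatol": 1e-6})
        d = float(res.x)
        if -res.fun < tol:
            break
        lam[j] += d
        eta = eta + d * f
        new_gain = penalized_gain(lam, eta)
        increments[j] += max(new_gain - gain, 0.0)
        gain = new_gain
    return lam, gain, increments


def fit_maxent(presences_lonlat: np.ndarray, rasters: list[Raster],
               reg: float = 1.0, seed: int | None = None,
               tol: float = 1e-6, max_iter: int = 1000) -> HabitatModel:
    """Fit the presence-only model.

    ``presences_lonlat`` is an (m, 2) array of lon/lat points; they are
    mapped to grid cells and deduplicated per cell.  The background is
    every cell of the shared grid where all predictors are finite.
    ``reg`` multiplies the per-feature L1 penalty
    ``max(sd_presence, 0.05) / sqrt(m)``.
    """
    grid = _check_stack(rasters)
    X_all = np.column_stack([r.values.ravel() for r in rasters])
    bg_ok = np.all(np.isfinite(X_all), axis=1)
    bg_idx = np.flatnonzero(bg_ok)
    X_bg = X_all[bg_idx]

    pts = np.asarray(presences_lonlat, dtype=float)
    row, col, inside = grid.index_of(pts[:, 0], pts[:, 1])
    if not inside.all():
        k = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"presence {k} at ({pts[k, 0]:.4f}, {pts[k, 1]:.4f}) "
                         "falls outside the study grid")
    flat = row * grid.ncols + col
    bad = ~bg_ok[flat]
    if bad.any():
        r, c = row[bad][0], col[bad][0]
        raise ValueError(f"non-finite predictor at presence cell (row {r}, col {c})")
    cells = np.unique(flat)  # duplicates removed
    if len(cells) < 10:
        raise ValueError("need at least 10 distinct presence cells")
    X_pres = X_all[cells]

    lo, hi = X_bg.min(axis=0), X_bg.max(axis=0)
    F_bg = _design(X_bg, lo, hi)
    F_pres = _design(X_pres, lo, hi)
    m = len(cells)
    beta = reg * np.maximum(F_pres.std(axis=0, ddof=0), 0.05) / np.sqrt(m)
    lam, gain, incr = _coordinate_descent(F_bg, F_pres.mean(axis=0), beta,
                                          tol=tol, max_iter=max_iter)
    eta = F_bg @ lam
    w = np.exp(eta - eta.max())
    q = w / w.sum()
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    var_names = [r.name for r in rasters]
    per_var = {v: float(incr[2 * i] + incr[2 * i + 1])
               for i, v in enumerate(var_names)}
    return HabitatModel(var_names=var_names, lambdas=lam, beta=beta,
                        scale_lo=lo, scale_hi=hi, grid=grid,
                        bg_flat_index=bg_idx, bg_X=X_bg, presence_cells=cells,
                        entropy=entropy, gain=gain, gain_increments=per_var,
                        reg=reg)


def presence_background_auc(model: HabitatModel, test_X: np.ndarray) -> float:
    """AUC of test presences against the full background (trapezoidal)."""
    scores = np.concatenate([model.linear_predictor(test_X),
                             model.linear_predictor(model.bg_X)])
    labels = np.concatenate([np.ones(len(test_X)), np.zeros(len(model.bg_X))])
    return float(roc_auc_score(labels, scores))


def auc_category(auc: float) -> str:
    for lo, label in AUC_CATEGORIES:
        if auc > lo:
            return label
    return "invalid"


@dataclass
class ModelEvaluation:
    """Replicate evaluation summary for one presence dataset."""

    auc_per_replicate: np.ndarray
    mean_auc: float
    category: str
    mean_prediction: Raster
    cv_prediction: Raster
    percent_contribution: dict
    permutation_contribution: dict
    jackknife: dict              # var -> {"alone": gain, "without": gain}
    full_gain: float
    n_replicates: int


def _normalize_pct(d: dict) -> dict:
    total = sum(d.values())
    if total <= 0:
        return {k: 100.0 / len(d) for k in d}
    return {k: 100.0 * v / total for k, v in d.items()}


def evaluate(presences_lonlat: np.ndarray, rasters: list[Raster],
             replicates: int = 50, test_fraction: float = 0.30,
             reg: float = 1.0, seed: int = 0) -> ModelEvaluation:
    """Replicate 70/30 evaluation of the suitability model.

    Per replicate: random split of presence points, fit on the training
    share, test AUC against the background.  Percent contributions are
    replicate-averaged coordinate-path gain shares; permutation
    contributions are replicate-averaged normalized AUC drops after
    permuting one variable's background+test values.  Jackknife gains
    (variable alone / all but one) are computed once on the full data.
    Bit-for-bit reproducible given (seed, replicates).
    """
    rng = np.random.default_rng(seed)
    pts = np.asarray(presences_lonlat, dtype=float)
    grid = _check_stack(rasters)
    var_names = [r.name for r in rasters]

    aucs, preds = [], []
    pct_acc = {v: [] for v in var_names}
    perm_acc = {v: [] for v in var_names}
    for rep in range(replicates):
        order = rng.permutation(len(pts))
        n_test = max(int(round(test_fraction * len(pts))), 1)
        test_pts, train_pts = pts[order[:n_test]], pts[order[n_test:]]
        try:
            model = fit_maxent(train_pts, rasters, reg=reg)
        except ValueError as exc:
            logger.warning("replicate %d skipped: %s", rep, exc)
            continue
        # test presences keep their multiplicity: held-out points are scored
        # as drawn (only training presences are deduplicated per cell)
        row, col, inside = grid.index_of(test_pts[:, 0], test_pts[:, 1])
        flat = row[inside] * grid.ncols + col[inside]
        X_all = np.column_stack([r.values.ravel() for r in rasters])
        ok = np.all(np.isfinite(X_all[flat]), axis=1)
        test_cells = flat[ok]
        if len(test_cells) < 2:
            logger.warning("replicate %d skipped: fewer than 2 usable test presences", rep)
            continue
        test_X = X_all[test_cells]
        aucs.append(presence_background_auc(model, test_X))
        preds.append(model.predict_raster(rasters).values)
        for v, share in _normalize_pct(model.gain_increments).items():
            pct_acc[v].append(share)
        # permutation importance: shuffle one raw variable over test+background rows
        base_auc = aucs[-1]
        comb = np.vstack([test_X, model.bg_X])
        n_t = len(test_X)
        for k, v in enumerate(var_names):
            perm = comb.copy()
            perm[:, k] = rng.permutation(perm[:, k])
            scores = model.linear_predictor(perm)
            labels = np.concatenate([np.ones(n_t), np.zeros(len(comb) - n_t)])
            drop = base_auc - float(roc_auc_score(labels, scores))
            perm_acc[v].append(max(drop, 0.0))
    if not aucs:
        raise ValueError("no replicate produced a usable test split")

    full = fit_maxent(pts, rasters, reg=reg)
    jack = {}
    for k, v in enumerate(var_names):
        alone = fit_maxent(pts, [rasters[k]], reg=reg)
        without = (fit_maxent(pts, [r for i, r in enumerate(rasters) if i != k],
                              reg=reg) if len(rasters) > 1 else None)
        jack[v] = {"alone": alone.gain,
                   "without": without.gain if without else 0.0}

    stack = np.stack(preds)
    mean_pred = np.nanmean(stack, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_pred = np.nanstd(stack, axis=0) / mean_pred
    mean_auc = float(np.mean(aucs))
    return ModelEvaluation(
        auc_per_replicate=np.asarray(aucs),
        mean_auc=mean_auc,
        category=auc_category(mean_auc),
        mean_prediction=Raster("mean_suitability", grid, mean_pred),
        cv_prediction=Raster("cv_suitability", grid, cv_pred),
        percent_contribution=_normalize_pct(
            {v: float(np.mean(s)) if s else 0.0 for v, s in pct_acc.items()}),
        permutation_contribution=_normalize_pct(
            {v: float(np.mean(s)) if s else 0.0 for v, s in perm_acc.items()}),
        jackknife=jack,
        full_gain=full.gain,
        n_replicates=len(aucs))
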