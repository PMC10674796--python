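"""Variography and ordinary kriging.

The spatial correlation of the survey variable is summarised by the
semivariogram γ(h) = E[(Z(x) − Z(x+h))²]/2, modelled here with the
spherical family (nugget c0, partial sill c, range a). Ordinary kriging
treats the local mean as an unknown constant and predicts each location
as a weighted average of its neighbours, with the weights solving the
semivariance-form kriging system under the unbiasedness constraint
Σ w_i = 1 (enforced through a Lagrange multiplier). The kriging variance
is σ²(x) = Σ w_i γ(x_i, x) + μ.

Spatial dependence strength is classed by the nugget-to-total-sill
percentage: ≤25 % strong, 25–75 % moderate, >75 % weak (Cambardella
convention).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .dataio import PointSurvey, RasterGrid

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "CrossValidationStats",
    "empirical_variogram",
    "spherical_gamma",
    "fit_variogram",
    "anisotropy_ratio",
    "ordinary_kriging",
    "loo_cross_validation",
    "nugget_sill_ratio",
    "summary_stats",
]


@dataclasses.dataclass
class EmpiricalVariogram:
    """Binned method-of-moments semivariance estimates."""

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    direction: float | None = None  # azimuth, degrees clockwise from north
    tolerance: float | None = None  # half-angle, degrees

    def __post_init__(self) -> None:
        self.lag_centers = np.asarray(self.lag_centers, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if not np.all(np.diff(self.lag_centers) > 0):
            raise ValueError("lag centers must be strictly increasing")
        if np.any(self.pair_counts < 1):
            raise ValueError("retained bins must have at least one pair")
        if np.any(~np.isfinite(self.gamma)) or np.any(self.gamma < 0):
            raise ValueError("semivariances must be finite and nonnegative")


@dataclasses.dataclass
class VariogramModel:
    """Spherical (or pure-nugget) variogram model.

    nugget : semivariance at h→0+ (c0)
    partial_sill : structured variance (c); total sill = c0 + c
    range_m : correlation range a in metres
    """

    nugget: float
    partial_sill: float
    range_m: float
    family: str = "spherical"
    range_identifiable: bool = True
    weighted_sse: float | None = None

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be nonnegative")
        if self.range_m <= 0:
            raise ValueError("range must be positive")
        if self.family not in {"spherical", "nugget"}:
            raise ValueError(f"unsupported family {self.family!r}")

    @property
    def total_sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h) -> np.ndarray:
        return spherical_gamma(self, h)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range_m": self.range_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(d["nugget"], d["partial_sill"], d["range_m"],
                   family=d.get("family", "spherical"))


@dataclasses.dataclass
class CrossValidationStats:
    """Leave-one-out kriging diagnostics.

    rmse is in survey units; mean_standardised_error is the mean of
    (Z* − Z)/SE and should be near 0 when the model is calibrated;
    effective prediction is flagged when rmse < the data SD.
    """

    rmse: float
    mean_error: float
    mean_standard_error: float
    mean_standardised_error: float
    data_sd: float
    mean_standardised_squared_error: float
    n: int

    @property
    def rmse_below_data_sd(self) -> bool:
        return self.rmse < self.data_sd


def spherical_gamma(model: VariogramModel, h) -> np.ndarray:
    """Evaluate the model semivariance at lag(s) h ≥ 0.

    γ(0) = 0; γ(h) = c0 + c(1.5 h/a − 0.5 (h/a)³) for 0 < h ≤ a;
    γ(h) = c0 + c beyond the range.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("lag distances must be nonnegative")
    hr = np.minimum(h / model.range_m, 1.0)
    gamma = model.nugget + model.partial_sill * (1.5 * hr - 0.5 * hr**3)
    return np.where(h == 0.0, 0.0, gamma)


def _pair_arrays(points: PointSurvey):
    d = pdist(points.coords)
    n = len(points)
    iu, ju = np.triu_indices(n, k=1)
    sq = 0.5 * (points.values[iu] - points.values[ju]) ** 2
    return d, sq, iu, ju


def empirical_variogram(
    points: PointSurvey,
    lag_width: float | None = None,
    max_lag: float | None = None,
    direction: float | None = None,
    tolerance: float = 22.5,
) -> EmpiricalVariogram:
    """Method-of-moments experimental variogram.

    γ(h_k) = (1/2N_k) Σ (z_i − z_j)² over the N_k pairs whose separation
    falls in bin k. Defaults: lag width twice the average
    nearest-neighbour spacing, maximum lag half the maximum pairwise
    distance. A ``direction`` (azimuth in degrees, clockwise from north)
    restricts pairs to a ± ``tolerance`` angular sector.
    """
    if len(points) < 2:
        raise ValueError("need at least two points")
    d, sq, iu, ju = _pair_arrays(points)
    if max_lag is None:
        max_lag = 0.5 * d.max()
    if lag_width is None:
        tree = cKDTree(points.coords)
        nn_dist, _ = tree.query(points.coords, k=2)
        lag_width = 2.0 * float(nn_dist[:, 1].mean())
    if lag_width <= 0 or max_lag <= lag_width:
        raise ValueError("need 0 < lag_width < max_lag")

    keep = d <= max_lag
    if direction is not None:
        dx = points.x[ju] - points.x[iu]
        dy = points.y[ju] - points.y[iu]
        az = np.degrees(np.arctan2(dx, dy)) % 180.0
        diff = np.abs(az - direction % 180.0)
        diff = np.minimum(diff, 180.0 - diff)
        keep &= diff <= tolerance
    d, sq = d[keep], sq[keep]
    if d.size == 0:
        raise ValueError("no point pair within max_lag (and direction sector)")

    edges = np.arange(0.0, max_lag + lag_width, lag_width)
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0,
                  len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=sq, minlength=len(edges) - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonempty = counts > 0
    return EmpiricalVariogram(
        centers[nonempty], sums[nonempty] / counts[nonempty],
        counts[nonempty], direction=direction,
        tolerance=tolerance if direction is not None else None,
    )


def _wls_objective(params, emp: EmpiricalVariogram) -> float:
    c0, c, a = params
    model = VariogramModel(max(c0, 0.0), max(c, 0.0), max(a, 1e-12))
    g = spherical_gamma(model, emp.lag_centers)
    g_safe = np.maximum(g, 1e-12)
    return float(np.sum(emp.pair_counts * (emp.gamma - g) ** 2 / g_safe**2))


def fit_variogram(
    emp: EmpiricalVariogram,
    family: str = "spherical",
    n_multistart: int = 5,
) -> VariogramModel:
    """Fit a spherical model by Cressie-weighted least squares.

    Minimises Σ N_k (γ̂_k − γ(h_k))² / γ(h_k)² over (c0, c, a) with
    nonnegativity bounds and a small multistart over initial ranges. A
    flat (pure-nugget) variogram yields c ≈ 0 with the range flagged
    unidentifiable.
    """
    if family != "spherical":
        raise ValueError("only the spherical family is supported")
    if len(emp.lag_centers) < 4:
        raise ValueError("need at least 4 variogram bins to fit")

    sill0 = float(np.mean(emp.gamma[-max(1, len(emp.gamma) // 3):]))
    sill0 = max(sill0, 1e-9)
    h_max = float(emp.lag_centers[-1])
    best = None
    rng_starts = np.linspace(0.2, 1.8, n_multistart) * 0.6 * h_max
    for a0 in rng_starts:
        for frac0 in (0.0, 0.3):
            x0 = [frac0 * sill0, (1 - frac0) * sill0, a0]
            res = optimize.minimize(
                _wls_objective, x0, args=(emp,),
                method="L-BFGS-B",
                bounds=[(0.0, None), (0.0, None), (1e-6, 10 * h_max)],
            )
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("variogram fit failed to converge")
    c0, c, a = best.x
    total = c0 + c
    identifiable = total > 0 and c / max(total, 1e-12) > 1e-3
    return VariogramModel(
        max(c0, 0.0), max(c, 0.0), max(a, 1e-6),
        family="spherical" if identifiable else "nugget",
        range_identifiable=bool(identifiable),
        weighted_sse=float(best.fun),
    )


def anisotropy_ratio(
    points: PointSurvey,
    n_directions: int = 4,
    lag_width: float | None = None,
    max_lag: float | None = None,
) -> tuple[float, float]:
    """Ratio of the longest to shortest directional variogram range.

    Fits directional variograms over ``n_directions`` evenly spaced
    azimuths and returns (max range / min range, azimuth of the major
    direction). A ratio near 1 supports the isotropy assumption.
    """
    if np.ptp(points.values) == 0:
        raise ValueError("constant field has no spatial structure")
    azimuths = np.arange(n_directions) * 180.0 / n_directions
    tol = 90.0 / n_directions
    ranges = []
    for az in azimuths:
        emp = empirical_variogram(points, lag_width=lag_width,
                                  max_lag=max_lag, direction=az,
                                  tolerance=tol)
        model = fit_variogram(emp)
        if not model.range_identifiable:
            raise ValueError(f"directional fit at azimuth {az} "
                             "has no spatial structure")
        ranges.append(model.range_m)
    ranges = np.asarray(ranges)
    major = float(azimuths[np.argmax(ranges)])
    return float(ranges.max() / ranges.min()), major


def _solve_ok(coords: np.ndarray, values: np.ndarray,
              target: np.ndarray, model: VariogramModel):
    """Solve one ordinary-kriging system; returns (estimate, variance, w, mu)."""
    n = coords.shape[0]
    if n == 1:
        g0 = float(spherical_gamma(
            model, np.linalg.norm(coords[0] - target)))
        return float(values[0]), 2 * g0, np.ones(1), -g0
    gamma_ij = spherical_gamma(model, squareform(pdist(coords)))
    a_mat = np.empty((n + 1, n + 1))
    a_mat[:n, :n] = gamma_ij
    a_mat[:n, n] = 1.0
    a_mat[n, :n] = 1.0
    a_mat[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = spherical_gamma(
        model, np.linalg.norm(coords - target, axis=1))
    b[n] = 1.0
    try:
        sol = np.linalg.solve(a_mat, b)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(a_mat, b, rcond=None)[0]
    w, mu = sol[:n], sol[n]
    est = float(w @ values)
    var = float(w @ b[:n] + mu)
    if var < 0:
        if var < -1e-8:
            warnings.warn("negative kriging variance clipped to 0")
        var = 0.0
    return est, var, w, mu


def ordinary_kriging(
    points: PointSurvey,
    model: VariogramModel,
    template: RasterGrid,
    max_neighbors: int = 16,
    search_radius: float | None = None,
) -> tuple[RasterGrid, RasterGrid]:
    """Krige a survey onto a raster; returns (estimate, standard error).

    Each cell is predicted from its ``max_neighbors`` nearest points
    within ``search_radius`` (default 1.5 × the model range). Cells with
    no neighbour in range get nodata. Duplicate coordinates are averaged
    beforehand so the kriging matrix stays nonsingular.
    """
    pts = points.averaged_duplicates()
    if search_radius is None:
        search_radius = 1.5 * model.range_m
    tree = cKDTree(pts.coords)
    gx, gy = template.cell_centers()
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    k = min(max_neighbors, len(pts))
    dist, idx = tree.query(targets, k=k)
    dist = np.atleast_2d(dist.reshape(len(targets), k))
    idx = np.atleast_2d(idx.reshape(len(targets), k))

    est = np.full(len(targets), np.nan)
    var = np.full(len(targets), np.nan)
    for row in range(len(targets)):
        in_range = dist[row] <= search_radius
        if not in_range.any():
            continue
        nbr = idx[row][in_range]
        e, v, _, _ = _solve_ok(
            pts.coords[nbr], pts.values[nbr], targets[row], model)
        est[row], var[row] = e, v
    if np.isnan(est).all():
        raise ValueError("no cell has a neighbour within the search radius")
    est_grid = template.like(est.reshape(template.shape))
    se_grid = template.like(np.sqrt(var).reshape(template.shape))
    est_grid.values[np.isnan(est_grid.values)] = est_grid.nodata
    se_grid.values[np.isnan(se_grid.values)] = se_grid.nodata
    return est_grid, se_grid


def krige_at_points(
    points: PointSurvey,
    model: VariogramModel,
    targets: np.ndarray,
    max_neighbors: int = 16,
    search_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Point-support kriging at arbitrary target coordinates."""
    pts = points.averaged_duplicates()
    if search_radius is None:
        search_radius = 1.5 * model.range_m
    tree = cKDTree(pts.coords)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    k = min(max_neighbors, len(pts))
    dist, idx = tree.query(targets, k=k)
    dist = dist.reshape(len(targets), k)
    idx = idx.reshape(len(targets), k)
    est = np.full(len(targets), np.nan)
    var = np.full(len(targets), np.nan)
    for row in range(len(targets)):
        in_range = dist[row] <= search_radius
        if not in_range.any():
            continue
        nbr = idx[row][in_range]
        est[row], var[row], _, _ = _solve_ok(
            pts.coords[nbr], pts.values[nbr], targets[row], model)
    return est, np.sqrt(var)


def loo_cross_validation(
    points: PointSurvey,
    model: VariogramModel,
    max_neighbors: int = 16,
    search_radius: float | None = None,
) -> CrossValidationStats:
    """Leave-one-out kriging diagnostics.

    Each datum is predicted from the remaining points; reports RMSE,
    mean error, mean kriging standard error, mean standardised error
    (Z*−Z)/SE, the mean standardised *squared* error (≈1 when the
    variogram is well calibrated) and the data SD for the
    rmse-below-SD effectiveness check.
    """
    pts = points.averaged_duplicates()
    n = len(pts)
    if n < max(10, max_neighbors + 1):
        raise ValueError("too few points for leave-one-out validation")
    if search_radius is None:
        search_radius = 1.5 * model.range_m
    tree = cKDTree(pts.coords)
    k = min(max_neighbors + 1, n)
    dist, idx = tree.query(pts.coords, k=k)
    errors = np.empty(n)
    ses = np.empty(n)
    for i in range(n):
        mask = (idx[i] != i) & (dist[i] <= search_radius)
        nbr = idx[i][mask][:max_neighbors]
        if nbr.size == 0:
            raise ValueError(f"point {i} has an empty LOO neighbourhood")
        est, var, _, _ = _solve_ok(
            pts.coords[nbr], pts.values[nbr], pts.coords[i], model)
        errors[i] = est - pts.values[i]
        ses[i] = np.sqrt(var)
    std_err = errors / np.where(ses > 0, ses, np.inf)
    return CrossValidationStats(
        rmse=float(np.sqrt(np.mean(errors**2))),
        mean_error=float(np.mean(errors)),
        mean_standard_error=float(np.mean(ses)),
        mean_standardised_error=float(np.mean(std_err)),
        data_sd=float(np.std(pts.values, ddof=1)),
        mean_standardised_squared_error=float(np.mean(std_err**2)),
        n=n,
    )


def nugget_sill_ratio(
    model: VariogramModel,
    strong_max: float = 25.0,
    moderate_max: float = 75.0,
) -> tuple[float, str]:
    """Nugget as a percentage of the total sill, with dependence class.

    Values at or below ``strong_max`` percent indicate strong spatial
    dependence, above ``moderate_max`` weak, in between moderate.
    """
    if model.total_sill <= 0:
        raise ValueError("total sill must be positive")
    pct = 100.0 * model.nugget / model.total_sill
    if pct <= strong_max:
        cls = "strong"
    elif pct <= moderate_max:
        cls = "moderate"
    else:
        cls = "weak"
    return pct, cls


def summary_stats(points: PointSurvey) -> dict:
    """Exploratory summary: mean, median, SD, CV%, skewness, kurtosis."""
    if len(points) < 2:
        raise ValueError("need at least two points")
    v = points.values
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if mean == 0:
        raise ValueError("coefficient of variation undefined at zero mean")
    return {
        "n": len(points),
        "mean": mean,
        "median": float(np.median(v)),
        "sd": sd,
        "cv_percent": 100.0 * sd / mean,
        "skewness": float(stats.skew(v, bias=False)),
        "kurtosis": float(stats.kurtosis(v, bias=False, fisher=False)),
        "min": float(v.min()),
        "max": float(v.max()),
    }
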