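"""Logger series to validated per-period temperature rasters.

The workflow mirrors standard cave-microclimate practice: hourly logger
series are reduced to daily means, each daily point set is augmented with
wall duplicates (two copies of every logger value placed perpendicular to
the passage just outside the walls, so the interpolated surface stays flat
across narrow corridors), a natural-neighbour (Sibson) surface is evaluated
on the boundary-clipped grid, and the daily fields are summarised per bat
activity period into the five statistic layers Tmin/Tmax/Tmean/Trange/Tstd
that form the SDM feature space. Interpolations are validated dependently
(leave-one-logger-out) and independently (against spot probe measurements),
both reported as MAE and RMSE.

The Sibson interpolator here is a *discrete* area-stealing implementation:
on a fine pixel lattice every pixel knows its nearest data point (its
Voronoi owner) and donates its area to any query cell closer to it than
that owner is. Stolen areas per owner, normalised, are exactly the Sibson
weights up to pixel discretisation. Weights depend only on the point
geometry, so one weight matrix serves every daily field of a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString, Point

from .cave_geometry import GeometryError, GridSpec, LevelGeometry

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_MONTHS = {
    "SO": frozenset({9, 10}),
    "NM": frozenset({11, 12, 1, 2, 3}),
    "AM": frozenset({4, 5}),
}


@dataclass(frozen=True)
class ActivityPeriod:
    """A bat activity period: SO (hibernation start, Sep-Oct), NM (mid-to-end
    hibernation, Nov-Mar) or AM (maternity start, Apr-May)."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in _MONTHS:
            raise ValueError(f"unknown activity period {self.code!r}")

    @property
    def months(self) -> frozenset[int]:
        return _MONTHS[self.code]

    def contains(self, when) -> bool:
        return pd.Timestamp(when).month in self.months


SO = ActivityPeriod("SO")
NM = ActivityPeriod("NM")
AM = ActivityPeriod("AM")
PERIODS = (SO, NM, AM)


@dataclass
class LoggerSeries:
    """Hourly temperature series from one data logger at a centerline station."""

    logger_id: str
    station_id: str
    level_index: int
    timestamps: pd.DatetimeIndex
    temps_C: np.ndarray
    stated_accuracy_C: float = 0.5
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temps_C = np.asarray(self.temps_C, dtype=float)
        if len(self.timestamps) != len(self.temps_C):
            raise ValueError("timestamps and temps_C lengths differ")
        if len(self.timestamps) == 0:
            raise ValueError("no data")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if np.nanmin(self.temps_C) < -30 or np.nanmax(self.temps_C) > 40:
            raise ValueError("temperatures outside physical range (-30..40 C)")
        if self.timestamps[-1] - self.timestamps[0] < pd.Timedelta(hours=23):
            raise ValueError("series must span at least one full day")
        if self.stated_accuracy_C <= 0:
            raise ValueError("stated_accuracy_C must be positive")


@dataclass
class PeriodRasterStack:
    """Per-cell Tmin/Tmax/Tmean/Trange/Tstd for one activity period."""

    period: ActivityPeriod
    grid: GridSpec
    layers: dict[str, np.ndarray]
    n_days: int = 0

    LAYER_NAMES = ("Tmin", "Tmax", "Tmean", "Trange", "Tstd")

    def __post_init__(self) -> None:
        for name in self.LAYER_NAMES:
            if name not in self.layers:
                raise ValueError(f"missing layer {name}")
        shp = (self.grid.n_rows, self.grid.n_cols)
        for name, arr in self.layers.items():
            if np.asarray(arr).shape != shp:
                raise ValueError(f"layer {name} shape mismatch")
        m = self.grid.inside_mask & ~np.isnan(self.layers["Tmean"])
        tmin, tmax = self.layers["Tmin"][m], self.layers["Tmax"][m]
        tmean, trange = self.layers["Tmean"][m], self.layers["Trange"][m]
        if not np.allclose(trange, tmax - tmin, atol=1e-6):
            raise ValueError("Trange must equal Tmax - Tmin cellwise")
        if np.any(tmin > tmean + 1e-9) or np.any(tmean > tmax + 1e-9):
            raise ValueError("Tmin <= Tmean <= Tmax violated")
        if np.any(self.layers["Tstd"][m] < -1e-12):
            raise ValueError("Tstd must be non-negative")

    def feature_table(self) -> np.ndarray:
        """(n_inside, 5) feature matrix in LAYER_NAMES order."""
        m = self.grid.inside_mask
        return np.column_stack([self.layers[n][m] for n in self.LAYER_NAMES])

    def features_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [self.layers[n][rows, cols] for n in self.LAYER_NAMES]
        )


@dataclass
class InterpolationValidation:
    mode: str  # "dependent" | "independent"
    MAE_C: float
    RMSE_C: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.MAE_C) and np.isfinite(self.RMSE_C)):
            raise ValueError("MAE/RMSE must be finite")
        if self.MAE_C > self.RMSE_C + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")


@dataclass
class DisturbanceReport:
    IST_C: float
    peak_excess_C: float
    recovery_hours: float | None  # None = not recovered

    def __post_init__(self) -> None:
        if self.peak_excess_C < 0:
            raise ValueError("peak_excess_C must be >= 0")
        if self.recovery_hours is not None and self.recovery_hours < 0:
            raise ValueError("recovery_hours must be >= 0")


@dataclass
class InterpolatedField:
    grid: GridSpec
    values: np.ndarray  # NaN outside the boundary
    extrapolated: np.ndarray  # QA flag: cells outside the data convex hull


# ---------------------------------------------------------------------------
# daily means
# ---------------------------------------------------------------------------


def compute_daily_means(
    series: LoggerSeries, min_coverage: float = 0.75
) -> tuple[pd.Series, list]:
    """Daily mean temperature per calendar day with sufficient hourly coverage.

    Days with fewer than ``min_coverage`` of 24 hourly records are excluded
    and returned in the second element.
    """
    if len(series.temps_C) == 0:
        raise ValueError("no data")
    s = pd.Series(series.temps_C, index=series.timestamps)
    by_day = s.groupby(s.index.date)
    counts = by_day.count()
    means = by_day.mean()
    keep = counts >= min_coverage * 24
    excluded = list(counts.index[~keep])
    return means[keep], excluded


# ---------------------------------------------------------------------------
# wall duplication
# ---------------------------------------------------------------------------


def duplicate_points_to_walls(
    points: np.ndarray,
    values: np.ndarray,
    level: LevelGeometry,
    offset_m: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Copy each interior point twice, perpendicular to the passage, just
    outside the cave walls.

    For every input point the nearest centerline segment defines the local
    passage direction; the point's value is copied onto two points placed
    along the perpendicular, each ``offset_m`` beyond the wall on its side.
    Returns ``(points3, values3, source_index)`` where ``source_index`` maps
    each output row to its input row (originals come first).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    boundary = level.boundary
    walls = boundary.boundary  # exterior (and hole) linework
    for i, (x, y) in enumerate(points):
        if not boundary.covers(Point(x, y)) or walls.distance(Point(x, y)) == 0:
            raise GeometryError(f"point outside cave: input point {i} at ({x}, {y})")

    segments = level.centerline_segments()
    if not segments:
        raise GeometryError("geometry error: level has no centerline edges")

    diameter = float(
        np.hypot(
            boundary.bounds[2] - boundary.bounds[0],
            boundary.bounds[3] - boundary.bounds[1],
        )
    )

    out_pts = [points]
    out_vals = [values]
    out_src = [np.arange(len(points))]
    for i, (x, y) in enumerate(points):
        a, b = _nearest_segment(points[i], segments)
        t = b - a
        norm = np.hypot(*t)
        normal = np.array([-t[1], t[0]]) / norm
        for sign in (+1.0, -1.0):
            dup = _offset_beyond_wall(
                np.array([x, y]), sign * normal, boundary, diameter, offset_m
            )
            out_pts.append(dup[None, :])
            out_vals.append(values[i : i + 1])
            out_src.append(np.array([i]))
    return (
        np.vstack(out_pts),
        np.concatenate(out_vals),
        np.concatenate(out_src),
    )


def _nearest_segment(p: np.ndarray, segments) -> tuple[np.ndarray, np.ndarray]:
    best, best_d = None, np.inf
    for a, b in segments:
        d = LineString([a, b]).distance(Point(p))
        if d < best_d:
            best, best_d = (a, b), d
    return best


def _offset_beyond_wall(
    p: np.ndarray, direction: np.ndarray, boundary, diameter: float, offset_m: float
) -> np.ndarray:
    """Walk from p along direction to the first wall crossing, then offset_m past it."""
    ray = LineString([p, p + direction * diameter])
    hit = ray.intersection(boundary.boundary)
    if hit.is_empty:
        # no wall in this direction (open side); fall back to a fixed offset
        return p + direction * offset_m
    d_hit = hit.distance(Point(p)) if hit.geom_type == "Point" else min(
        g.distance(Point(p)) for g in getattr(hit, "geoms", [hit])
    )
    return p + direction * (d_hit + offset_m)


# ---------------------------------------------------------------------------
# discrete Sibson natural-neighbour interpolation
# ---------------------------------------------------------------------------


@dataclass
class SibsonWeights:
    """Natural-neighbour weight matrix for a fixed point geometry on a grid.

    ``W[q, i]`` is the Sibson weight of data point i at inside cell q
    (row-major over inside cells); rows sum to 1. ``extrapolated`` flags
    cells outside the convex hull of the points (served by nearest
    neighbour). Reuse the matrix across any number of value vectors sharing
    the same point locations.
    """

    grid: GridSpec
    points: np.ndarray
    W: np.ndarray
    extrapolated: np.ndarray  # (n_inside,) bool

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Interpolate a value vector into a full 2-D field (NaN outside)."""
        values = np.asarray(values, dtype=float)
        out = self.grid.empty_field()
        out[self.grid.inside_mask] = self.W @ values
        return out


def sibson_weights(
    points: np.ndarray,
    grid: GridSpec,
    supersample: int = 1,
    snap_tol_m: float = 1e-6,
) -> SibsonWeights:
    """Compute discrete Sibson weights from scattered points to grid cells.

    ``supersample`` refines the pixel lattice relative to the grid (odd
    values keep cell centers on the lattice). The stolen-area construction
    is clipped to the padded grid bounding box, i.e. the Voronoi diagram is
    implicitly box-clipped — the standard finite treatment.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    _check_support(points)
    queries = grid.inside_centers()
    W = _stolen_area_weights_grid(points, grid, supersample)
    extrapolated = _outside_hull(points, queries)
    _apply_fallbacks(W, points, queries, extrapolated, snap_tol_m)
    return SibsonWeights(grid, points, W, extrapolated)


def sibson_weights_at(
    points: np.ndarray,
    queries: np.ndarray,
    pixel_size: float,
    snap_tol_m: float = 1e-6,
) -> np.ndarray:
    """Sibson weight rows for arbitrary query points (used by validation)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    _check_support(points)
    W = np.vstack(
        [_stolen_area_row(points, q, pixel_size) for q in queries]
    )
    extrapolated = _outside_hull(points, queries)
    _apply_fallbacks(W, points, queries, extrapolated, snap_tol_m)
    return W


def _check_support(points: np.ndarray) -> None:
    if len(points) < 3:
        raise ValueError("insufficient support: need at least 3 points")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("insufficient support: points are collinear")


def _outside_hull(points: np.ndarray, queries: np.ndarray) -> np.ndarray:
    try:
        tri = Delaunay(points)
    except Exception:  # degenerate configurations
        return np.ones(len(queries), dtype=bool)
    return tri.find_simplex(queries) < 0


def _apply_fallbacks(
    W: np.ndarray,
    points: np.ndarray,
    queries: np.ndarray,
    extrapolated: np.ndarray,
    snap_tol_m: float,
) -> None:
    """Normalise rows; nearest-neighbour rows outside the hull; exact snap
    where a query coincides with a data point."""
    tree = cKDTree(points)
    d_near, i_near = tree.query(queries)
    row_sum = W.sum(axis=1)
    empty = row_sum <= 0
    ok = ~empty
    W[ok] /= row_sum[ok, None]
    one_hot = empty | extrapolated | (d_near <= snap_tol_m)
    if one_hot.any():
        W[one_hot] = 0.0
        W[np.nonzero(one_hot)[0], i_near[one_hot]] = 1.0


def _stolen_area_weights_grid(
    points: np.ndarray, grid: GridSpec, supersample: int = 1
) -> np.ndarray:
    """Discrete Sibson area stealing on the grid's own pixel lattice.

    Each lattice pixel x, owned by its nearest data point o(x) at distance
    d(x), donates its area to every query cell q with |x - q| < d(x). The
    donated areas per owner are the (unnormalised) Sibson weights of q.
    Pixels are bucketed by integer disk radius so the scatter runs as one
    vectorised accumulation per (radius, lattice offset) pair.
    """
    if supersample < 1 or supersample % 2 == 0:
        raise ValueError("supersample must be an odd positive integer")
    ss = supersample
    pixel = grid.cell_size_m / ss
    n_pr, n_pc = grid.n_rows * ss, grid.n_cols * ss
    # pixel centers; cell (r, c) center is pixel (r*ss + ss//2, c*ss + ss//2)
    px_x = grid.origin[0] + (np.arange(n_pc) + 0.5) * pixel
    px_y = grid.origin[1] + (n_pr - np.arange(n_pr) - 0.5) * pixel
    xx, yy = np.meshgrid(px_x, px_y)
    pts_flat = np.column_stack([xx.ravel(), yy.ravel()])

    tree = cKDTree(points)
    d_own, owner = tree.query(pts_flat)

    # query index per pixel: the inside-cell index at cell-center pixels
    qidx = np.full((n_pr, n_pc), -1, dtype=np.int64)
    rows, cols = np.nonzero(grid.inside_mask)
    qidx[rows * ss + ss // 2, cols * ss + ss // 2] = np.arange(len(rows))

    # cap the stolen-cell radius at the largest query-to-site distance:
    # larger radii only occur for padding pixels outside the data hull
    centers = grid.inside_centers()
    d_q, _ = tree.query(centers)
    r_cap = float(d_q.max()) + pixel
    radii_px = np.minimum(d_own, r_cap) / pixel  # in pixel units
    k = np.floor(radii_px).astype(np.int64)  # integer disk radius class

    W = np.zeros((len(centers), len(points)))
    area = pixel**2
    d_own2 = d_own  # noqa: F841  (kept for clarity)

    owner_grid = owner.reshape(n_pr, n_pc)
    k_grid = k.reshape(n_pr, n_pc)
    for kk in np.unique(k_grid):
        if kk <= 0:
            continue
        pr, pc = np.nonzero(k_grid == kk)
        own = owner_grid[pr, pc]
        rng = np.arange(-kk, kk + 1)
        di, dj = np.meshgrid(rng, rng)
        keep = di**2 + dj**2 < kk**2
        for a, b in zip(di[keep].ravel(), dj[keep].ravel()):
            rr, cc = pr + a, pc + b
            ok = (rr >= 0) & (rr < n_pr) & (cc >= 0) & (cc < n_pc)
            qi = qidx[rr[ok], cc[ok]]
            hit = qi >= 0
            if hit.any():
                np.add.at(W, (qi[hit], own[ok][hit]), area)
    return W


def _stolen_area_row(
    points: np.ndarray, q: np.ndarray, pixel_size: float
) -> np.ndarray:
    """Unnormalised Sibson weights of a single arbitrary query point.

    Scans a local pixel disk around the query, growing the radius until the
    stolen region {x : |x - q| < d(x)} is fully contained, clipped to the
    padded bounding box of the data points (box-clipped Voronoi)."""
    tree = cKDTree(points)
    lo = points.min(axis=0) - 2 * pixel_size
    hi = points.max(axis=0) + 2 * pixel_size
    lo, hi = np.minimum(lo, q - 2 * pixel_size), np.maximum(hi, q + 2 * pixel_size)
    d_q = float(tree.query(q)[0])
    R = max(2 * d_q, 4 * pixel_size)
    diag = float(np.hypot(*(hi - lo)))
    w = np.zeros(len(points))
    while True:
        xs = np.arange(q[0] - R, q[0] + R, pixel_size) + pixel_size / 2
        ys = np.arange(q[1] - R, q[1] + R, pixel_size) + pixel_size / 2
        xs = xs[(xs >= lo[0]) & (xs <= hi[0])]
        ys = ys[(ys >= lo[1]) & (ys <= hi[1])]
        if len(xs) == 0 or len(ys) == 0:
            return w
        xxg, yyg = np.meshgrid(xs, ys)
        px = np.column_stack([xxg.ravel(), yyg.ravel()])
        dist_q = np.hypot(px[:, 0] - q[0], px[:, 1] - q[1])
        d_own, owner = tree.query(px)
        stolen = (dist_q < d_own) & (dist_q < R)
        # grown enough when no stolen pixel touches the scan boundary
        if not (stolen & (dist_q > R - 2 * pixel_size)).any() or R > diag:
            w[:] = 0.0
            np.add.at(w, owner[stolen], pixel_size**2)
            return w
        R *= 2.0


def interpolate_field(
    points: np.ndarray,
    values: np.ndarray,
    grid: GridSpec,
    weights: SibsonWeights | None = None,
    supersample: int = 2,
) -> InterpolatedField:
    """Natural-neighbour surface of scattered values on the boundary grid.

    Pass a precomputed :class:`SibsonWeights` to amortise the geometric work
    across many daily value vectors. The result is NaN outside the boundary,
    bounded by the input value range, and flagged where the grid extends
    beyond the convex hull of the (wall-augmented) points.
    """
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = sibson_weights(points, grid, supersample=supersample)
    out = weights.apply(values)
    flag = np.zeros_like(grid.inside_mask)
    flag[grid.inside_mask] = weights.extrapolated
    return InterpolatedField(grid, out, flag)


# ---------------------------------------------------------------------------
# period statistics
# ---------------------------------------------------------------------------


def build_period_stack(
    daily_fields: Mapping, period: ActivityPeriod, grid: GridSpec
) -> PeriodRasterStack:
    """Summarise daily temperature fields into the five period statistics.

    ``daily_fields`` maps dates to 2-D fields on ``grid``. Only dates whose
    month belongs to the period are used. Statistics are computed across the
    daily (mean) fields: Tmin/Tmax are extremes of daily means, Tstd is the
    population standard deviation.
    """
    dates = [d for d in daily_fields if period.contains(d)]
    if not dates:
        raise ValueError(f"empty period: no days fall in {period.code}")
    stackarr = np.stack([np.asarray(daily_fields[d], dtype=float) for d in dates])
    flat = stackarr[:, grid.inside_mask]
    shape = (grid.n_rows, grid.n_cols)

    def full(vals):
        out = np.full(shape, np.nan)
        out[grid.inside_mask] = vals
        return out

    with np.errstate(invalid="ignore"):
        tmin = full(np.nanmin(flat, axis=0))
        tmax = full(np.nanmax(flat, axis=0))
        tmean = full(np.nanmean(flat, axis=0))
        tstd = full(np.nanstd(flat, axis=0, ddof=0))
    layers = {
        "Tmin": tmin,
        "Tmax": tmax,
        "Tmean": tmean,
        "Trange": tmax - tmin,
        "Tstd": tstd,
    }
    outside = ~grid.inside_mask
    for arr in layers.values():
        arr[outside] = np.nan
    return PeriodRasterStack(period, grid, layers, n_days=len(dates))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _mae_rmse(residuals: np.ndarray) -> tuple[float, float]:
    residuals = np.asarray(residuals, dtype=float)
    return float(np.mean(np.abs(residuals))), float(np.sqrt(np.mean(residuals**2)))


def dependent_validation(
    logger_points: np.ndarray,
    logger_values: np.ndarray,
    level: LevelGeometry,
    pixel_size: float = 0.25,
    offset_m: float = 0.25,
) -> InterpolationValidation:
    """Leave-one-logger-out cross-validation of the interpolation.

    For each logger the surface is rebuilt from the remaining loggers only —
    the held-out logger's wall duplicates are removed along with it, so no
    information leaks — and evaluated at the held-out location.

    ``logger_values`` may be a 1-D vector (one field) or a 2-D
    ``(n_days, n_loggers)`` matrix; with a matrix the leave-one-out weights
    are reused across days and residuals pooled over all (day, logger)
    pairs.
    """
    logger_points = np.atleast_2d(np.asarray(logger_points, dtype=float))
    vals = np.asarray(logger_values, dtype=float)
    one_d = vals.ndim == 1
    if one_d:
        vals = vals[None, :]
    n = logger_points.shape[0]
    if vals.shape[1] != n:
        raise ValueError("logger_values last axis must match logger count")
    if n < 4:
        raise ValueError("insufficient loggers: dependent validation needs >= 4")
    residuals = np.empty((vals.shape[0], n))
    for i in range(n):
        keep = np.arange(n) != i
        # geometry is day-independent: wall-duplicate the positions once
        pts3, _v, src = duplicate_points_to_walls(
            logger_points[keep], vals[0, keep], level, offset_m
        )
        w = sibson_weights_at(pts3, logger_points[i : i + 1], pixel_size)[0]
        kept_idx = np.arange(n)[keep]
        vals3 = vals[:, kept_idx[src]]  # (n_days, 3*(n-1)) duplicated values
        residuals[:, i] = vals3 @ w - vals[:, i]
    residuals = residuals.ravel() if not one_d else residuals[0]
    mae, rmse = _mae_rmse(residuals)
    return InterpolationValidation("dependent", mae, rmse, residuals)


def independent_validation(
    field: InterpolatedField | np.ndarray,
    grid: GridSpec,
    spot_points: np.ndarray,
    spot_values: np.ndarray,
) -> InterpolationValidation:
    """Compare the interpolated surface with spot probe measurements."""
    values = field.values if isinstance(field, InterpolatedField) else np.asarray(field)
    spot_points = np.atleast_2d(np.asarray(spot_points, dtype=float))
    spot_values = np.asarray(spot_values, dtype=float)
    preds = []
    for (x, y), obs in zip(spot_points, spot_values):
        r, c = grid.xy_to_rc(x, y)
        if not grid.contains_rc(r, c) or not grid.inside_mask[r, c]:
            r, c, _ = grid.nearest_inside_cell(x, y)
        preds.append(values[r, c] - obs)
    residuals = np.asarray(preds)
    residuals = residuals[np.isfinite(residuals)]
    if len(residuals) == 0:
        raise ValueError("no spot measurement falls inside the mask")
    mae, rmse = _mae_rmse(residuals)
    return InterpolationValidation("independent", mae, rmse, residuals)


def validate_interpolation(mode: str, **kwargs) -> InterpolationValidation:
    """Dispatch to dependent or independent validation by mode name."""
    if mode == "dependent":
        return dependent_validation(**kwargs)
    if mode == "independent":
        return independent_validation(**kwargs)
    raise ValueError(f"unknown validation mode {mode!r}")


# ---------------------------------------------------------------------------
# disturbance recovery
# ---------------------------------------------------------------------------


def disturbance_recovery(
    series: LoggerSeries,
    disturbance_start,
    tolerance_C: float = 0.1,
    baseline_days: int = 7,
    sustain_hours: int = 6,
) -> DisturbanceReport:
    """Detect recovery to the initial stable temperature after a disturbance.

    IST is the median of the pre-disturbance baseline window. Peak excess is
    the largest exceedance above IST after the disturbance starts; recovery
    time is measured from the peak to the first instant from which the
    series stays within ``tolerance_C`` of IST for at least
    ``sustain_hours`` consecutive hourly records.
    """
    t0 = pd.Timestamp(disturbance_start)
    ts, temps = series.timestamps, series.temps_C
    base = (ts >= t0 - pd.Timedelta(days=baseline_days)) & (ts < t0)
    if base.sum() < 24:
        raise ValueError("baseline too short: need >= 24 h before the disturbance")
    ist = float(np.median(temps[base]))

    post = ts >= t0
    post_t, post_v = ts[post], temps[post]
    if len(post_v) == 0:
        raise ValueError("no data after disturbance start")
    excess = post_v - ist
    peak_excess = float(max(excess.max(), 0.0))
    if peak_excess <= tolerance_C:
        return DisturbanceReport(ist, peak_excess, 0.0)

    peak_idx = int(np.argmax(excess))
    within = np.abs(excess) <= tolerance_C
    run = 0
    for j in range(peak_idx + 1, len(within)):
        run = run + 1 if within[j] else 0
        if run >= sustain_hours:
            start = j - sustain_hours + 1
            hours = (post_t[start] - post_t[peak_idx]) / pd.Timedelta(hours=1)
            return DisturbanceReport(ist, peak_excess, float(hours))
    return DisturbanceReport(ist, peak_excess, None)
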