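"""Seeded generator of synthetic caves, thermal regimes and bat colonies.

No machine-readable raw field data accompany the study this pipeline
serves, so the generator emulates the statistical structure the pipeline
assumes and carries the ground truth needed for parameter-recovery tests:

- corridor-shaped cave polygons built from a meandering centerline, with
  1-2 entrances and optionally a second overlapping level;
- a temperature field whose variability decays exponentially with
  within-cave distance from the entrance, ``T(cell, day) = T_deep +
  (T_ext(day) - T_ext_mean) * exp(-d / lambda) + noise``, so that the deep
  cave reflects the exterior annual mean (static climate, < 5 degC annual
  range) while entrance sectors track the exterior sinusoid (dynamic
  climate);
- hourly logger series sampled from the true field at stations 2 m above
  the floor, plus spot measurements carrying a bounded vertical-gradient
  offset (<= 0.9 degC);
- heavily clustered occurrences from a Thomas-style cluster process whose
  parent intensity follows a known Gaussian suitability response over the
  period temperature statistics;
- tourist-pass counts, with the 100-passes-per-year placeholder for
  non-touristic sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .cave_geometry import (
    CaveMap,
    DistanceField,
    Entrance,
    GeometryError,
    GridSpec,
    LevelGeometry,
    distance_from_entrance,
    rasterize_boundary,
)
from .microclimate import (
    AM,
    NM,
    PERIODS,
    SO,
    ActivityPeriod,
    LoggerSeries,
    PeriodRasterStack,
    build_period_stack,
)
from .esdm_engine import OccurrenceSet

logger = logging.getLogger(__name__)

NON_TOURISTIC_PASSES = 100  # placeholder pass count for unmonitored sites


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesResponse:
    """Known Gaussian suitability response of a synthetic species.

    ``optima`` maps period-statistic layer names to (mu, sigma) of a
    Gaussian response; the true suitability is the normalised product of
    the per-layer responses.
    """

    name: str
    period: ActivityPeriod
    optima: Mapping[str, tuple[float, float]]


def _default_species() -> tuple[SpeciesResponse, ...]:
    # hibernating species: cold mid-hibernation optimum (5 degC, the classic
    # rhinolophid torpor preference) with a penalty on thermally dynamic
    # sectors; places the suitable band in the cave interior, between the
    # dynamic entrance zone and the warmer deep static zone
    return (
        SpeciesResponse(
            "Synthetic hibernator", NM, {"Tmin": (5.0, 1.0), "Trange": (0.0, 3.0)}
        ),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of the default synthetic scenario.

    Sized for desk scale: a 200 m corridor at 0.5 m cells (a few thousand
    inside cells), 12 loggers, 300 clustered occurrences.
    """

    seed: int = 0
    # geometry
    corridor_length_m: float = 200.0
    corridor_width_m: float = 4.0
    width_jitter_m: float = 1.0
    n_levels: int = 1
    n_entrances: int = 1
    cell_size_m: float = 0.5
    station_spacing_m: float = 5.0
    # thermal regime
    t_deep_C: float = 9.0
    exterior_mean_C: float = 9.0
    exterior_amplitude_C: float = 8.0
    decay_length_m: float = 50.0
    noise_sd_C: float = 0.1
    # loggers; spacing follows the expected thermal-amplitude gradient
    # (denser near the entrance where the exterior signal decays fastest)
    n_loggers: int = 12
    logger_spacing: str = "equal_amplitude"  # or "uniform"
    logger_noise_sd_C: float = 0.05
    # colonies: occurrence records accumulate over repeated field visits,
    # so clusters ~ visits x roost patches, not simultaneous colonies
    species: tuple[SpeciesResponse, ...] = field(default_factory=_default_species)
    n_colonies: int = 15
    colony_dispersion_m: float = 4.0
    occurrences_total: int = 300
    # spot measurements / tourists
    vertical_gradient_max_C: float = 0.9
    probe_noise_sd_C: float = 0.1
    touristic: bool = False
    passes_per_period: Mapping[str, int] = field(
        default_factory=lambda: {"SO": 100, "NM": 100, "AM": 100}
    )
    # simulated span: one full year covering all three activity periods
    start_date: str = "2015-06-01"
    n_days: int = 365

    def __post_init__(self) -> None:
        if self.decay_length_m <= 0:
            raise ValueError("decay_length_m must be > 0")
        if self.exterior_amplitude_C < 0:
            raise ValueError("exterior_amplitude_C must be >= 0")
        if self.colony_dispersion_m <= 0:
            raise ValueError("colony_dispersion_m must be > 0")
        if min(self.n_loggers, self.n_colonies, self.occurrences_total) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_levels not in (1, 2) or self.n_entrances not in (1, 2):
            raise ValueError("n_levels and n_entrances must be 1 or 2")


@dataclass
class TruthBundle:
    """Everything the pipeline sees plus the ground truth it should recover."""

    config: ScenarioConfig
    cave: CaveMap
    grid: GridSpec
    distance: DistanceField
    true_daily_fields: dict  # date -> 2-D field (degC), noise-free + noise
    true_stacks: dict[str, PeriodRasterStack]
    true_suitability: dict[tuple[str, str], np.ndarray]  # (species, period) -> field
    loggers: list[LoggerSeries]
    logger_positions: np.ndarray
    exterior: pd.Series
    occurrences: list[OccurrenceSet]
    spot_measurements: pd.DataFrame
    passes: dict[str, int]


# ---------------------------------------------------------------------------
# cave generation
# ---------------------------------------------------------------------------


def _meander_centerline(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded meandering polyline of total length ~ corridor_length_m.

    The polyline must not approach itself closer than ~2.5 corridor widths
    (a corridor cave keeps rock between its passages; a self-touching
    buffer would merge passages and break the within-cave distance model),
    so candidates are redrawn — with gradually straightened headings —
    until the separation constraint holds.
    """
    step = 2.0
    n_steps = int(round(config.corridor_length_m / step))
    # passages must keep enough rock between them that a logger's own
    # neighbours stay closer than any foreign passage (wall-duplicate
    # shielding): at least ~4 corridor widths
    min_sep = 4.0 * (config.corridor_width_m + config.width_jitter_m)
    turn_sd = 0.12
    for attempt in range(40):
        heading = rng.uniform(0, 2 * np.pi)
        pts = [np.zeros(2)]
        turn = 0.0
        for _ in range(n_steps):
            turn = 0.7 * turn + rng.normal(0, turn_sd)
            turn = float(np.clip(turn, -0.3, 0.3))
            heading += turn
            pts.append(pts[-1] + step * np.array([np.cos(heading), np.sin(heading)]))
        line = np.asarray(pts)
        if _self_separated(line, step, min_sep):
            return line
        if attempt % 5 == 4:
            turn_sd *= 0.7
            logger.info("centerline self-approach; straightening (sd=%.3f)", turn_sd)
    return line  # last resort: near-straight corridor always passes


def _self_separated(line: np.ndarray, step: float, min_sep: float) -> bool:
    """True when non-adjacent vertices keep at least ``min_sep`` apart."""
    window = max(2, int(np.ceil(2 * min_sep / step)))  # skip near-neighbours
    d = np.sqrt(((line[:, None, :] - line[None, :, :]) ** 2).sum(-1))
    idx = np.abs(np.arange(len(line))[:, None] - np.arange(len(line))[None, :])
    far_pairs = idx > window
    return bool((d[far_pairs] >= min_sep).all())


def _corridor_polygon(
    line: np.ndarray, config: ScenarioConfig, rng: np.random.Generator
) -> Polygon:
    """Union of per-segment buffers with jittered half-widths."""
    jitter = config.width_jitter_m
    for attempt in range(4):
        parts = []
        for a, b in zip(line[:-1], line[1:]):
            half = max(
                0.5, config.corridor_width_m / 2 + rng.normal(0, jitter / 2)
            )
            parts.append(LineString([a, b]).buffer(half, quad_segs=4))
        poly = unary_union(parts)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        poly = Polygon(poly.exterior)  # drop pinched-off interior holes
        if poly.is_valid and poly.area > 0:
            return poly
        logger.info("corridor polygon invalid; retrying with reduced jitter")
        jitter *= 0.5
    raise GeometryError("geometry error: could not build a valid corridor polygon")


def generate_cave(config: ScenarioConfig, seed: int | None = None) -> CaveMap:
    """Deterministic synthetic cave: meandering corridor, stations, entrances."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    levels, entrances = [], []
    offset = np.zeros(2)
    for lvl in range(1, config.n_levels + 1):
        line = _meander_centerline(config, rng) + offset
        poly = _corridor_polygon(line, config, rng)
        g = nx.Graph()
        # stations every station_spacing_m of along-path distance
        step = 2.0
        every = max(1, int(round(config.station_spacing_m / step)))
        idxs = list(range(0, len(line), every))
        if idxs[-1] != len(line) - 1:
            idxs.append(len(line) - 1)
        prev = None
        for k, i in enumerate(idxs):
            p = line[i]
            if not poly.covers(Point(p)):
                continue  # jittered walls may pinch; skip rare outliers
            sid = f"L{lvl}S{k}"
            g.add_node(sid, pos=(float(p[0]), float(p[1])))
            if prev is not None:
                length = float(
                    np.linalg.norm(line[i] - line[prev_i])
                )
                g.add_edge(prev, sid, length=length)
            prev, prev_i = sid, i
        levels.append(LevelGeometry(lvl, poly, g))

        # entrances on the boundary at the corridor end(s)
        from shapely.ops import nearest_points

        ends = [0] if config.n_entrances == 1 or lvl > 1 else [0, len(line) - 1]
        for j, i in enumerate(ends):
            on_wall, _ = nearest_points(poly.boundary, Point(line[i]))
            entrances.append(
                Entrance(f"L{lvl}E{j}", float(on_wall.x), float(on_wall.y), lvl)
            )
        # a second level overlaps the deep end, shifted laterally
        offset = line[-1] - line[len(line) // 2] + np.array([0.0, 2 * config.corridor_width_m])

    return CaveMap(
        site_id=f"synthetic-{config.seed}",
        name="Synthetic corridor cave",
        levels=levels,
        entrances=entrances,
        cavity_type="show_cave" if config.touristic else "wild_cave",
        cave_length_m=config.corridor_length_m * config.n_levels,
        tourist_passes_per_year=(
            sum(config.passes_per_period.values())
            if config.touristic
            else NON_TOURISTIC_PASSES
        ),
    )


# ---------------------------------------------------------------------------
# thermal regime
# ---------------------------------------------------------------------------


def exterior_series(config: ScenarioConfig) -> pd.Series:
    """Pure annual sinusoid of daily exterior temperature (no weather noise)."""
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    # peak near late July (day ~205)
    temps = config.exterior_mean_C + config.exterior_amplitude_C * np.cos(
        2 * np.pi * (doy - 205) / 365.25
    )
    return pd.Series(temps, index=dates)


def simulate_temperatures(
    cave: CaveMap,
    grid: GridSpec,
    distance: DistanceField,
    config: ScenarioConfig,
    seed: int | None = None,
) -> tuple[dict, list[LoggerSeries], np.ndarray, pd.Series]:
    """True daily temperature fields plus hourly logger series.

    Field model: ``T(cell, day) = T_deep + (T_ext(day) - T_ext_mean) *
    exp(-d(cell) / lambda) + eps`` with spatially white daily noise. Loggers
    sit at evenly spaced centerline stations and record their cell's series
    hourly with instrument noise.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    ext = exterior_series(config)
    mask = grid.inside_mask
    d = distance.values[mask]
    d = np.where(np.isfinite(d), d, np.nanmax(d[np.isfinite(d)] if np.isfinite(d).any() else 0))
    damp = np.exp(-d / config.decay_length_m)

    fields = {}
    for date, t_ext in ext.items():
        vals = (
            config.t_deep_C
            + (t_ext - config.exterior_mean_C) * damp
            + rng.normal(0, config.noise_sd_C, size=damp.shape)
        )
        f = grid.empty_field()
        f[mask] = vals
        fields[date.date()] = f

    # logger placement along the level-1 centerline, ordered by along-path
    # distance from the entrance-end station
    lv = cave.levels[0]
    stations = lv.stations
    path_d = np.array(
        [
            nx.shortest_path_length(
                lv.centerline, stations[0].station_id, s.station_id, weight="length"
            )
            if nx.has_path(lv.centerline, stations[0].station_id, s.station_id)
            else 0.0
            for s in stations
        ]
    )
    order = np.argsort(path_d)
    stations = [stations[i] for i in order]
    path_d = path_d[order]
    if config.logger_spacing == "equal_amplitude":
        # equal increments of a blend of along-path position and decayed
        # exterior amplitude: denser where the thermal gradient is steep
        # while still covering the deep static zone (no unmonitored gaps)
        lam = config.decay_length_m
        span = max(path_d[-1], 1.0)
        amp = np.exp(-path_d / lam)
        u = 0.5 * (1 - path_d / span) + 0.5 * (amp - amp[-1]) / max(
            amp[0] - amp[-1], 1e-9
        )
        targets = np.linspace(u[0], u[-1], config.n_loggers)
        used: list[int] = []
        for t in targets:
            cost = np.abs(u - t)
            cost[used] = np.inf
            used.append(int(np.argmin(cost)))
        pick = np.unique(used)
    else:
        pick = np.unique(
            np.linspace(0, len(stations) - 1, config.n_loggers).round().astype(int)
        )
    chosen = [stations[i] for i in pick]

    hours = pd.date_range(
        config.start_date, periods=config.n_days * 24, freq="h"
    )
    day_keys = list(fields)
    loggers, positions = [], []
    for j, st in enumerate(chosen):
        r, c, _ = grid.nearest_inside_cell(st.x, st.y)
        daily = np.array([fields[k][r, c] for k in day_keys])
        hourly = np.repeat(daily, 24) + rng.normal(
            0, config.logger_noise_sd_C, size=len(hours)
        )
        loggers.append(
            LoggerSeries(
                logger_id=f"LOG{j}",
                station_id=st.station_id,
                level_index=st.level_index,
                timestamps=hours,
                temps_C=np.clip(hourly, -29.9, 39.9),
                stated_accuracy_C=max(config.logger_noise_sd_C, 0.01),
                position=(st.x, st.y),
            )
        )
        positions.append([st.x, st.y])
    return fields, loggers, np.asarray(positions), ext


# ---------------------------------------------------------------------------
# suitability and occurrences
# ---------------------------------------------------------------------------


def define_true_suitability(
    stack: PeriodRasterStack, response: SpeciesResponse
) -> np.ndarray:
    """Product of Gaussian responses over the chosen layers, max-normalised."""
    grid = stack.grid
    suit = np.ones((grid.n_rows, grid.n_cols))
    for layer, (mu, sigma) in response.optima.items():
        vals = stack.layers[layer]
        suit = suit * np.exp(-((vals - mu) ** 2) / (2 * sigma**2))
    suit[~grid.inside_mask] = np.nan
    peak = np.nanmax(suit)
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("true suitability is degenerate (all zero)")
    return suit / peak


def sample_occurrences(
    suitability: np.ndarray,
    grid: GridSpec,
    config: ScenarioConfig,
    species: str,
    period: ActivityPeriod,
    seed: int | None = None,
    site_id: str = "synthetic",
) -> OccurrenceSet:
    """Thomas-style cluster process over the true suitability surface.

    Colony parents are drawn with probability proportional to suitability;
    offspring scatter around parents with isotropic Gaussian dispersion and
    are rejected outside the mask. Each point carries a small colony tally
    (count >= 1).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    mask = grid.inside_mask
    weights = np.where(np.isnan(suitability), 0.0, suitability)[mask]
    if weights.sum() <= 0:
        raise ValueError("true suitability is degenerate (all zero)")
    centers = grid.inside_centers()
    p = weights / weights.sum()
    parent_idx = rng.choice(len(centers), size=config.n_colonies, p=p)
    parents = centers[parent_idx]

    per_cluster = np.full(config.n_colonies, config.occurrences_total // config.n_colonies)
    per_cluster[: config.occurrences_total % config.n_colonies] += 1

    suit_flat = np.where(np.isnan(suitability), 0.0, suitability)
    rows = []
    for parent, n_off in zip(parents, per_cluster):
        # colony tallies share a per-cluster scale: records of the same
        # colony carry similar counts, as repeated field tallies do, and
        # larger colonies form in better habitat (counts track suitability)
        pr, pc = grid.xy_to_rc(*parent)
        s_parent = float(suit_flat[pr, pc])
        colony_scale = float(
            np.clip(rng.lognormal(np.log(1.0 + 6.0 * s_parent), 0.5), 1.0, 20.0)
        )
        placed = 0
        while placed < n_off:
            cand = parent + rng.normal(0, config.colony_dispersion_m, size=2)
            r, c = grid.xy_to_rc(*cand)
            if grid.contains_rc(r, c) and mask[r, c]:
                rows.append(
                    {
                        "site_id": site_id,
                        "level_index": 1,
                        "x": cand[0],
                        "y": cand[1],
                        "count": max(1, int(rng.poisson(colony_scale))),
                    }
                )
                placed += 1
    return OccurrenceSet(species, period, pd.DataFrame(rows))


def simulate_spot_and_passes(
    occurrences: Sequence[OccurrenceSet],
    stacks: Mapping[str, PeriodRasterStack],
    distance: DistanceField,
    config: ScenarioConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Spot measurements at occurrence points plus per-period pass counts.

    Spot temperature = true cell Tmean of the period + a vertical-gradient
    offset bounded by ``vertical_gradient_max_C`` + probe noise. Sites that
    are not tourist-monitored receive the flat placeholder of
    100 passes per period.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 3)
    rows = []
    for occ in occurrences:
        stack = stacks[occ.period.code]
        for _, rec in occ.records.iterrows():
            r, c = stack.grid.xy_to_rc(rec["x"], rec["y"])
            t_cell = stack.layers["Tmean"][r, c]
            offset = rng.uniform(0, config.vertical_gradient_max_C)
            rows.append(
                {
                    "x": rec["x"],
                    "y": rec["y"],
                    "level_index": rec["level_index"],
                    "species": occ.species,
                    "period": occ.period.code,
                    "temp_C": t_cell + offset + rng.normal(0, config.probe_noise_sd_C),
                    "true_cell_temp_C": t_cell,
                    "height_m": float(rng.uniform(1.0, 6.0)),
                    "distance_entrance_m": float(distance.values[r, c]),
                    "count": int(rec["count"]),
                }
            )
    spots = pd.DataFrame(rows)
    if config.touristic:
        passes = {k: int(v) for k, v in config.passes_per_period.items()}
    else:
        passes = {p.code: NON_TOURISTIC_PASSES for p in PERIODS}
    return spots, passes


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


def build_truth_bundle(config: ScenarioConfig) -> TruthBundle:
    """Generate the full synthetic scenario with its ground truth."""
    cave = generate_cave(config)
    grid = rasterize_boundary(cave.levels[0], config.cell_size_m)
    distance = distance_from_entrance(cave, grid, level_index=1)
    fields, loggers, logger_pos, ext = simulate_temperatures(
        cave, grid, distance, config
    )
    stacks = {}
    for per in PERIODS:
        try:
            stacks[per.code] = build_period_stack(fields, per, grid)
        except ValueError:
            continue
    suitability = {}
    occurrences = []
    for resp in config.species:
        stack = stacks[resp.period.code]
        suit = define_true_suitability(stack, resp)
        suitability[(resp.name, resp.period.code)] = suit
        occurrences.append(
            sample_occurrences(
                suit, grid, config, resp.name, resp.period, site_id=cave.site_id
            )
        )
    spots, passes = simulate_spot_and_passes(
        occurrences, stacks, distance, config
    )
    return TruthBundle(
        config=config,
        cave=cave,
        grid=grid,
        distance=distance,
        true_daily_fields=fields,
        true_stacks=stacks,
        true_suitability=suitability,
        loggers=loggers,
        logger_positions=logger_pos,
        exterior=ext,
        occurrences=occurrences,
        spot_measurements=spots,
        passes=passes,
    )
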