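"""Spatial scaffolding for subterranean sites.

A cave (or mine) is modelled as one or more *levels*, each a simple polygon
in a local planar coordinate system (metres) with a surveyed centerline graph
of stations, plus entrance points. All modelling happens on a regular grid
clipped to the cave walls; within-cave distances are shortest paths over the
8-connected lattice of inside cells, mirroring how path distances behave in
narrow corridors.

Conventions: local planar coordinates per site (no geographic CRS); raster
cells use cell-center containment (boundary ties count as inside); 0-based
row/column indexing with row 0 at the top of the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString, MultiPolygon, Point, Polygon, shape

NODATA = -9999.0


class SchemaError(ValueError):
    """Input source is missing a required layer/field (schema error)."""


class GeometryError(ValueError):
    """A geometry violates an invariant (geometry error)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Station:
    station_id: str
    x: float
    y: float
    level_index: int

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Entrance:
    entrance_id: str
    x: float
    y: float
    level_index: int

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class LevelGeometry:
    """One cave level: boundary polygon(s) and its centerline station graph.

    The centerline is a networkx graph whose nodes are station ids with a
    ``pos`` attribute; edge lengths (metres) are stored as ``length``.
    """

    level_index: int
    boundary: Polygon | MultiPolygon
    centerline: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if self.boundary.is_empty or self.boundary.area <= 0:
            raise GeometryError(
                f"geometry error: level {self.level_index} boundary has no area"
            )
        if not self.boundary.is_valid:
            raise GeometryError(
                f"geometry error: level {self.level_index} boundary is invalid "
                "(self-intersecting?)"
            )
        for sid, data in self.centerline.nodes(data=True):
            pos = data.get("pos")
            if pos is None:
                raise SchemaError(f"schema error: station {sid} has no position")
            if not self.boundary.covers(Point(pos)):
                raise GeometryError(
                    f"geometry error: station {sid} lies outside the level "
                    f"{self.level_index} boundary"
                )
        if self.centerline.number_of_nodes() > 1 and not nx.is_connected(
            self.centerline
        ):
            raise GeometryError(
                f"geometry error: level {self.level_index} centerline is disconnected"
            )

    @property
    def stations(self) -> list[Station]:
        return [
            Station(sid, data["pos"][0], data["pos"][1], self.level_index)
            for sid, data in self.centerline.nodes(data=True)
        ]

    def centerline_segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Centerline edges as coordinate pairs (used for wall-perpendicular work)."""
        segs = []
        for u, v in self.centerline.edges():
            a = np.asarray(self.centerline.nodes[u]["pos"], dtype=float)
            b = np.asarray(self.centerline.nodes[v]["pos"], dtype=float)
            segs.append((a, b))
        return segs


@dataclass
class CaveMap:
    site_id: str
    name: str
    levels: list[LevelGeometry]
    entrances: list[Entrance]
    cavity_type: str = "wild_cave"
    cave_length_m: float = 1.0
    altitude_m: float | None = None
    tourist_passes_per_year: int = 0

    _CAVITY_TYPES = ("wild_cave", "show_cave", "artificial")

    def __post_init__(self) -> None:
        if not self.levels:
            raise SchemaError("schema error: cave has no levels")
        if not self.entrances:
            raise SchemaError("schema error: cave has no entrances")
        if self.cavity_type not in self._CAVITY_TYPES:
            raise SchemaError(
                f"schema error: cavity_type {self.cavity_type!r} not in "
                f"{self._CAVITY_TYPES}"
            )
        if not self.cave_length_m > 0:
            raise SchemaError("schema error: cave_length_m must be positive")
        if self.tourist_passes_per_year < 0:
            raise SchemaError("schema error: tourist_passes_per_year must be >= 0")
        ids = [e.entrance_id for e in self.entrances]
        if len(ids) != len(set(ids)):
            raise SchemaError("schema error: duplicate entrance ids")
        by_level = {lv.level_index: lv for lv in self.levels}
        for ent in self.entrances:
            lv = by_level.get(ent.level_index)
            if lv is None:
                raise SchemaError(
                    f"schema error: entrance {ent.entrance_id} references missing "
                    f"level {ent.level_index}"
                )

    def level(self, level_index: int) -> LevelGeometry:
        for lv in self.levels:
            if lv.level_index == level_index:
                return lv
        raise KeyError(level_index)


@dataclass
class GridSpec:
    """Regular analysis grid clipped to the cave boundary.

    ``origin`` is the lower-left corner of the lower-left cell. Row 0 is the
    TOP row, so the center of cell (r, c) is
    ``(origin_x + (c + 0.5) * cell, origin_y + (n_rows - r - 0.5) * cell)``.
    """

    origin: tuple[float, float]
    cell_size_m: float
    n_rows: int
    n_cols: int
    inside_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")
        self.inside_mask = np.asarray(self.inside_mask, dtype=bool)
        if self.inside_mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("inside_mask shape must be (n_rows, n_cols)")
        if not self.inside_mask.any():
            raise GeometryError("geometry error: grid has no inside cells")

    @property
    def n_inside(self) -> int:
        return int(self.inside_mask.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, shape (n_rows, n_cols)."""
        cs = self.cell_size_m
        x = self.origin[0] + (np.arange(self.n_cols) + 0.5) * cs
        y = self.origin[1] + (self.n_rows - np.arange(self.n_rows) - 0.5) * cs
        return np.meshgrid(x, y)

    def inside_centers(self) -> np.ndarray:
        """(n_inside, 2) array of inside cell-center coordinates (row-major order)."""
        xx, yy = self.cell_centers()
        return np.column_stack([xx[self.inside_mask], yy[self.inside_mask]])

    def xy_to_rc(self, x: float, y: float) -> tuple[int, int]:
        cs = self.cell_size_m
        c = int(np.floor((x - self.origin[0]) / cs))
        r = self.n_rows - 1 - int(np.floor((y - self.origin[1]) / cs))
        return r, c

    def contains_rc(self, r: int, c: int) -> bool:
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def nearest_inside_cell(self, x: float, y: float) -> tuple[int, int, float]:
        """Nearest inside cell to (x, y); returns (row, col, center distance in m)."""
        xx, yy = self.cell_centers()
        d2 = (xx - x) ** 2 + (yy - y) ** 2
        d2 = np.where(self.inside_mask, d2, np.inf)
        r, c = np.unravel_index(int(np.argmin(d2)), d2.shape)
        return int(r), int(c), float(np.sqrt(d2[r, c]))

    def empty_field(self) -> np.ndarray:
        out = np.full((self.n_rows, self.n_cols), np.nan)
        return out


@dataclass
class DistanceField:
    """Within-cave distance (m) from the nearest entrance, per inside cell."""

    grid: GridSpec
    values: np.ndarray  # NaN outside mask and at unreachable cells
    unreachable: np.ndarray  # bool: inside cells with no path to an entrance

    @property
    def n_unreachable(self) -> int:
        return int(self.unreachable.sum())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_REQUIRED_LAYERS = ("boundaries", "centerline", "entrances")


def load_cave_map(vector_source: str | Path | Mapping) -> CaveMap:
    """Load a :class:`CaveMap` from a layered GeoJSON source.

    The source is a JSON document (path or already-parsed mapping) with
    site-level fields (``site_id``, ``name``, ``cavity_type``, ``metadata``)
    and a ``layers`` mapping holding one GeoJSON FeatureCollection per layer:

    - ``boundaries``: Polygon features tagged with ``level_index``;
    - ``centerline``: Point features (stations, with ``station_id`` and
      ``level_index``) and LineString features (passages, with
      ``from_station`` / ``to_station``);
    - ``entrances``: Point features with ``entrance_id`` and ``level_index``.

    Coordinates are carried through unchanged (float64, i.e. well below
    millimetre round-off at cave scale).
    """
    if isinstance(vector_source, (str, Path)):
        with open(vector_source) as fh:
            doc = json.load(fh)
    else:
        doc = dict(vector_source)

    layers = doc.get("layers")
    if layers is None:
        raise SchemaError("schema error: source has no 'layers' mapping")
    for name in _REQUIRED_LAYERS:
        if name not in layers:
            raise SchemaError(f"schema error: missing layer {name!r}")

    # boundaries per level
    boundaries: dict[int, list[Polygon]] = {}
    for feat in layers["boundaries"].get("features", []):
        geom = shape(feat["geometry"])
        lvl = int(feat.get("properties", {}).get("level_index", 1))
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise SchemaError("schema error: boundary feature is not polygonal")
        if not geom.is_valid:
            fid = feat.get("properties", {}).get("id", "<unnamed>")
            raise GeometryError(
                f"geometry error: boundary feature {fid} (level {lvl}) is invalid"
            )
        polys = [geom] if isinstance(geom, Polygon) else list(geom.geoms)
        boundaries.setdefault(lvl, []).extend(polys)
    if not boundaries:
        raise SchemaError("schema error: boundaries layer holds no polygons")

    # centerline: stations + passages
    graphs: dict[int, nx.Graph] = {lvl: nx.Graph() for lvl in boundaries}
    station_level: dict[str, int] = {}
    for feat in layers["centerline"].get("features", []):
        props = feat.get("properties", {})
        geom = shape(feat["geometry"])
        if isinstance(geom, Point):
            sid = props.get("station_id")
            if sid is None:
                raise SchemaError("schema error: station feature without station_id")
            if sid in station_level:
                raise SchemaError(f"schema error: duplicate station id {sid!r}")
            lvl = int(props.get("level_index", 1))
            if lvl not in graphs:
                raise SchemaError(
                    f"schema error: station {sid} references missing level {lvl}"
                )
            graphs[lvl].add_node(sid, pos=(geom.x, geom.y))
            station_level[sid] = lvl
    for feat in layers["centerline"].get("features", []):
        props = feat.get("properties", {})
        geom = shape(feat["geometry"])
        if isinstance(geom, LineString):
            u, v = props.get("from_station"), props.get("to_station")
            if u not in station_level or v not in station_level:
                raise SchemaError(
                    f"schema error: passage references unknown stations {u!r}/{v!r}"
                )
            lvl = station_level[u]
            graphs[lvl].add_edge(u, v, length=float(geom.length))

    levels = []
    for lvl in sorted(boundaries):
        polys = boundaries[lvl]
        boundary = polys[0] if len(polys) == 1 else MultiPolygon(polys)
        levels.append(LevelGeometry(lvl, boundary, graphs[lvl]))

    entrances = []
    for feat in layers["entrances"].get("features", []):
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        eid = props.get("entrance_id")
        if eid is None or not isinstance(geom, Point):
            raise SchemaError("schema error: entrance feature malformed")
        entrances.append(Entrance(eid, geom.x, geom.y, int(props.get("level_index", 1))))

    meta = doc.get("metadata", {})
    return CaveMap(
        site_id=doc.get("site_id", "site"),
        name=doc.get("name", doc.get("site_id", "site")),
        levels=levels,
        entrances=entrances,
        cavity_type=doc.get("cavity_type", "wild_cave"),
        cave_length_m=float(meta.get("cave_length_m", 1.0)),
        altitude_m=meta.get("altitude_m"),
        tourist_passes_per_year=int(meta.get("tourist_passes_per_year", 0)),
    )


def save_cave_map(cave: CaveMap, path: str | Path) -> None:
    """Write a CaveMap back to the layered-GeoJSON form read by load_cave_map."""

    def fc(features: list[dict]) -> dict:
        return {"type": "FeatureCollection", "features": features}

    bnd, cl, ent = [], [], []
    for lv in cave.levels:
        bnd.append(
            {
                "type": "Feature",
                "properties": {"level_index": lv.level_index},
                "geometry": shapely.geometry.mapping(lv.boundary),
            }
        )
        for sid, data in lv.centerline.nodes(data=True):
            cl.append(
                {
                    "type": "Feature",
                    "properties": {"station_id": sid, "level_index": lv.level_index},
                    "geometry": {"type": "Point", "coordinates": list(data["pos"])},
                }
            )
        for u, v in lv.centerline.edges():
            coords = [list(lv.centerline.nodes[u]["pos"]), list(lv.centerline.nodes[v]["pos"])]
            cl.append(
                {
                    "type": "Feature",
                    "properties": {"from_station": u, "to_station": v},
                    "geometry": {"type": "LineString", "coordinates": coords},
                }
            )
    for e in cave.entrances:
        ent.append(
            {
                "type": "Feature",
                "properties": {"entrance_id": e.entrance_id, "level_index": e.level_index},
                "geometry": {"type": "Point", "coordinates": [e.x, e.y]},
            }
        )
    doc = {
        "site_id": cave.site_id,
        "name": cave.name,
        "cavity_type": cave.cavity_type,
        "metadata": {
            "cave_length_m": cave.cave_length_m,
            "altitude_m": cave.altitude_m,
            "tourist_passes_per_year": cave.tourist_passes_per_year,
        },
        "layers": {"boundaries": fc(bnd), "centerline": fc(cl), "entrances": fc(ent)},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def rasterize_boundary(
    level: LevelGeometry, cell_size_m: float = 0.5, padding_cells: int = 1
) -> GridSpec:
    """Rasterize a level boundary onto a regular grid.

    A cell is inside iff its CENTER is covered by the boundary polygon
    (boundary ties count as inside). The grid tightly bounds the polygon
    plus ``padding_cells`` of padding on every side.
    """
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be > 0")
    poly = level.boundary
    if poly.area < cell_size_m**2:
        raise GeometryError("degenerate boundary: polygon smaller than one cell")
    minx, miny, maxx, maxy = poly.bounds
    pad = padding_cells * cell_size_m
    origin = (
        np.floor((minx - pad) / cell_size_m) * cell_size_m,
        np.floor((miny - pad) / cell_size_m) * cell_size_m,
    )
    n_cols = int(np.ceil((maxx + pad - origin[0]) / cell_size_m))
    n_rows = int(np.ceil((maxy + pad - origin[1]) / cell_size_m))
    cs = cell_size_m
    x = origin[0] + (np.arange(n_cols) + 0.5) * cs
    y = origin[1] + (n_rows - np.arange(n_rows) - 0.5) * cs
    xx, yy = np.meshgrid(x, y)
    shapely.prepare(poly)
    pts = shapely.points(xx.ravel(), yy.ravel())
    mask = shapely.covers(poly, pts).reshape(n_rows, n_cols)
    return GridSpec(origin, cell_size_m, n_rows, n_cols, mask)


# offsets for 8-connected moves: (dr, dc, step length factor)
_MOVES = [
    (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
    (-1, -1, np.sqrt(2)), (-1, 1, np.sqrt(2)), (1, -1, np.sqrt(2)), (1, 1, np.sqrt(2)),
]


def distance_from_entrance(
    cave: CaveMap,
    grid: GridSpec,
    level_index: int | None = None,
    entrance_snap_tolerance_cells: float = 1.5,
) -> DistanceField:
    """Shortest within-cave path length (m) from each inside cell to an entrance.

    Paths move between 8-connected inside cells (diagonal step = cell·sqrt 2).
    Entrances are snapped to the nearest inside cell; an entrance farther than
    ``entrance_snap_tolerance_cells`` cells from any inside cell is ignored.
    Inside cells with no path to any entrance are flagged, not set to infinity.
    """
    if level_index is None:
        entrances = cave.entrances
    else:
        entrances = [e for e in cave.entrances if e.level_index == level_index]

    sources = []
    cs = grid.cell_size_m
    for ent in entrances:
        r, c, d = grid.nearest_inside_cell(ent.x, ent.y)
        if d <= entrance_snap_tolerance_cells * cs:
            sources.append((r, c))
    if not sources:
        raise GeometryError(
            "unreachable component: no entrance maps to an inside cell"
        )

    mask = grid.inside_mask
    idx = np.full(mask.shape, -1, dtype=np.int64)
    idx[mask] = np.arange(grid.n_inside)
    rows, cols = np.nonzero(mask)

    # sparse 8-connected lattice graph over inside cells
    data, ii, jj = [], [], []
    for dr, dc, w in _MOVES:
        r2, c2 = rows + dr, cols + dc
        ok = (r2 >= 0) & (r2 < grid.n_rows) & (c2 >= 0) & (c2 < grid.n_cols)
        ok[ok] &= mask[r2[ok], c2[ok]]
        ii.append(idx[rows[ok], cols[ok]])
        jj.append(idx[r2[ok], c2[ok]])
        data.append(np.full(ok.sum(), w * cs))
    graph = coo_matrix(
        (np.concatenate(data), (np.concatenate(ii), np.concatenate(jj))),
        shape=(grid.n_inside, grid.n_inside),
    ).tocsr()

    src = [int(idx[r, c]) for r, c in sources]
    dist = dijkstra(graph, directed=False, indices=src, min_only=True)

    values = grid.empty_field()
    values[mask] = dist
    unreachable = np.zeros_like(mask)
    unreachable[mask] = ~np.isfinite(dist)
    values[unreachable] = np.nan
    return DistanceField(grid, values, unreachable)


def merge_levels(
    fields: Mapping[int, np.ndarray], priority_level: int
) -> np.ndarray:
    """Merge per-level fields sharing one grid footprint into a single field.

    Where exactly one level has data (non-NaN) that value is used; where
    several overlap the ``priority_level`` value wins (remaining ties resolved
    by ascending level index); where none has data the cell stays NaN.
    """
    if not fields:
        raise ValueError("grid mismatch: no fields to merge")
    shapes = {np.asarray(f).shape for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("grid mismatch: fields have different shapes")
    if priority_level not in fields:
        raise ValueError(f"priority level {priority_level} not among fields")

    order = [priority_level] + sorted(k for k in fields if k != priority_level)
    out = np.full(shapes.pop(), np.nan)
    for lvl in order:
        f = np.asarray(fields[lvl], dtype=float)
        take = np.isnan(out) & ~np.isnan(f)
        out[take] = f[take]
    return out


# ---------------------------------------------------------------------------
# raster I/O — ESRI ASCII grid (plain text, row 0 at top)
# ---------------------------------------------------------------------------


def write_ascii_grid(
    path: str | Path, grid: GridSpec, values: np.ndarray, nodata: float = NODATA
) -> None:
    """Write a field as an ESRI ASCII grid (.asc). Rows run top to bottom."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("grid mismatch: values shape does not match grid")
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size_m:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6f")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header["nodata_value"]
    values[values == nodata] = np.nan
    grid = GridSpec(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size_m=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        inside_mask=~np.isnan(values),
    )
    return grid, values
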