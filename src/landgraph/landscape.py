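"""Raster overlays of population-graph edges and landscape permutation tests.

Each retained edge of the population graph is overlaid on a co-registered
raster as a straight-line *supercover* transect — the sequence of every
pixel the segment between the two locales touches.  Continuous layers are
summarized per edge by the mean and (population) variance of the traversed
pixel values; categorical layers by per-class pixel proportions.  The
landscape permutation test asks whether the observed popgraph's edges sit on
systematically different landscape values than degree-preserving rewirings
of the same graph with node positions held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import DegenerateInputError, PairwiseMatrix, PermutationResult, spawn_rng
from .netmetrics import degree_preserving_null

__all__ = [
    "RasterLayer",
    "read_ascii_grid",
    "geographic_distance_matrix",
    "extract_transect",
    "Transect",
    "edge_resistance_summary",
    "categorical_edge_profile",
    "aggregate_statistic",
    "landscape_permutation_test",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class RasterLayer:
    """Georeferenced grid, continuous or categorical.

    The geotransform is row-major with the origin at the *top-left* corner:
    world x increases with columns, world y decreases with rows.  ``nodata``
    pixels are excluded from all statistics.
    """

    grid: np.ndarray
    x_origin: float
    y_origin: float
    pixel_size: float
    nodata: float = -9999.0
    kind: str = "continuous"
    class_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or min(self.grid.shape) < 1:
            raise ValueError("raster grid must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if self.kind == "categorical":
            valid = self.grid[self.grid != self.nodata]
            if valid.size and not np.allclose(valid, np.round(valid)):
                raise ValueError("categorical raster carries non-integer codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def world_to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """Continuous (row, col) pixel coordinates of a world point."""
        col = (x - self.x_origin) / self.pixel_size
        row = (self.y_origin - y) / self.pixel_size
        return row, col

    def contains(self, x: float, y: float) -> bool:
        r, c = self.world_to_pixel(x, y)
        nr, nc = self.grid.shape
        return 0.0 <= r <= nr and 0.0 <= c <= nc

    # -- ESRI ASCII grid I/O ----------------------------------------------

    def write_ascii_grid(self, path: str | Path) -> None:
        nr, nc = self.grid.shape
        yll = self.y_origin - nr * self.pixel_size
        out = np.where(np.isnan(self.grid), self.nodata, self.grid)
        with open(path, "w") as fh:
            fh.write(f"ncols {nc}\n")
            fh.write(f"nrows {nr}\n")
            fh.write(f"xllcorner {float(self.x_origin)!r}\n")
            fh.write(f"yllcorner {float(yll)!r}\n")
            fh.write(f"cellsize {float(self.pixel_size)!r}\n")
            fh.write(f"NODATA_value {float(self.nodata)!r}\n")
            for row in out:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(
    path: str | Path, kind: str = "continuous", class_table: dict | None = None
) -> RasterLayer:
    """Read an ESRI ASCII grid (plain-text raster interchange format)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = np.asarray(rows, dtype=float)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if grid.shape != (nr, nc):
        raise ValueError(f"grid shape {grid.shape} != header ({nr}, {nc})")
    cell = header["cellsize"]
    return RasterLayer(
        grid=grid,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nr * cell,
        pixel_size=cell,
        nodata=header.get("nodata_value", -9999.0),
        kind=kind,
        class_table=class_table or {},
    )


# ---------------------------------------------------------------------------
# geographic distance
# ---------------------------------------------------------------------------


def geographic_distance_matrix(
    locales: pd.DataFrame, mode: str = "euclidean"
) -> PairwiseMatrix:
    """Pairwise locale distances from a (locale_id, x, y) table.

    ``euclidean`` operates on the coordinates as given (planar map units);
    ``haversine`` treats x as longitude and y as latitude in degrees and
    returns great-circle km on a sphere of radius 6371 km.  Duplicate
    coordinates are allowed (distance 0) with a warning.
    """
    ids = list(locales["locale_id"].astype(str))
    xy = locales[["x", "y"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValueError("locale coordinates must be finite")
    if mode == "euclidean":
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    elif mode == "haversine":
        lon = np.radians(xy[:, 0])
        lat = np.radians(xy[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    iu = np.triu_indices(len(ids), 1)
    if np.any(d[iu] == 0.0):
        warnings.warn("locales at identical coordinates (distance 0)")
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(ids, d, f"geo_{mode}")


# ---------------------------------------------------------------------------
# supercover transects
# ---------------------------------------------------------------------------


@dataclass
class Transect:
    """Pixel values along one straight locale-to-locale segment.

    ``values`` excludes nodata pixels; ``n_pixels`` counts every pixel the
    segment touched, ``n_nodata`` how many of those were nodata.
    """

    values: np.ndarray
    n_pixels: int
    n_nodata: int
    cells: list[tuple[int, int]]


def _supercover_cells(r0: float, c0: float, r1: float, c1: float, nr: int, nc: int):
    """Every grid cell a segment touches (Amanatides–Woo traversal)."""

    def clamp(i: int, n: int) -> int:
        return min(max(i, 0), n - 1)

    row, col = clamp(int(np.floor(r0)), nr), clamp(int(np.floor(c0)), nc)
    row_end, col_end = clamp(int(np.floor(r1)), nr), clamp(int(np.floor(c1)), nc)
    cells = [(row, col)]
    dr, dc = r1 - r0, c1 - c0
    step_r = 1 if dr > 0 else -1
    step_c = 1 if dc > 0 else -1
    # parametric distance to the next row/col boundary, in units of t ∈ [0,1]
    t_max_r = np.inf if dr == 0 else ((row + (step_r > 0)) - r0) / dr
    t_max_c = np.inf if dc == 0 else ((col + (step_c > 0)) - c0) / dc
    t_delta_r = np.inf if dr == 0 else abs(1.0 / dr)
    t_delta_c = np.inf if dc == 0 else abs(1.0 / dc)
    guard = 4 * (nr + nc) + 8
    while (row, col) != (row_end, col_end) and guard > 0:
        guard -= 1
        if t_max_r < t_max_c:
            row += step_r
            t_max_r += t_delta_r
        else:
            col += step_c
            t_max_c += t_delta_c
        row, col = clamp(row, nr), clamp(col, nc)
        cells.append((row, col))
    return cells


def extract_transect(raster: RasterLayer, a, b) -> Transect:
    """Supercover pixel traversal of the segment from point ``a`` to ``b``.

    Points are world coordinates in the raster's CRS (no reprojection);
    both must fall inside the raster extent.  Raises if every traversed
    pixel is nodata.
    """
    for name, pt in (("a", a), ("b", b)):
        if not raster.contains(*pt):
            raise ValueError(f"point {name}={pt} outside raster extent")
    nr, nc = raster.grid.shape
    r0, c0 = raster.world_to_pixel(*a)
    r1, c1 = raster.world_to_pixel(*b)
    cells = _supercover_cells(r0, c0, r1, c1, nr, nc)
    vals = np.asarray([raster.grid[r, c] for r, c in cells], dtype=float)
    ok = (vals != raster.nodata) & ~np.isnan(vals)
    if not ok.any():
        raise DegenerateInputError("all traversed pixels are nodata")
    return Transect(
        values=vals[ok],
        n_pixels=len(cells),
        n_nodata=int((~ok).sum()),
        cells=cells,
    )


# ---------------------------------------------------------------------------
# per-edge summaries
# ---------------------------------------------------------------------------


def _edge_pairs(graph_or_pairs) -> list[tuple[str, str]]:
    if isinstance(graph_or_pairs, nx.Graph):
        return [tuple(map(str, e)) for e in graph_or_pairs.edges()]
    return [tuple(map(str, p)) for p in graph_or_pairs]


def _coords(locales: pd.DataFrame) -> dict[str, tuple[float, float]]:
    return {
        str(r.locale_id): (float(r.x), float(r.y)) for r in locales.itertuples()
    }


def edge_resistance_summary(
    raster: RasterLayer, graph_or_pairs, locales: pd.DataFrame
) -> pd.DataFrame:
    """Mean and population variance of transect pixel values per edge.

    Fully-nodata edges propagate as NaN rows flagged by ``missing=True``.
    """
    if raster.kind != "continuous":
        raise ValueError("resistance summary applies to continuous rasters")
    pos = _coords(locales)
    rows = []
    for a, b in _edge_pairs(graph_or_pairs):
        try:
            t = extract_transect(raster, pos[a], pos[b])
            rows.append(
                dict(
                    locale_a=a,
                    locale_b=b,
                    n_pixels=t.values.size,
                    mean=float(t.values.mean()),
                    variance=float(t.values.var()),
                    missing=False,
                )
            )
        except DegenerateInputError:
            warnings.warn(f"edge ({a},{b}) entirely nodata; flagged missing")
            rows.append(
                dict(locale_a=a, locale_b=b, n_pixels=0, mean=np.nan,
                     variance=np.nan, missing=True)
            )
    return pd.DataFrame(rows)


def categorical_edge_profile(
    raster: RasterLayer, graph_or_pairs, locales: pd.DataFrame
) -> pd.DataFrame:
    """Per-edge class proportions of traversed (non-nodata) pixels.

    Proportions are reported in columns ``class_<code>`` and sum to 1 over
    the classes observed on that edge.
    """
    if raster.kind != "categorical":
        raise ValueError("class profile applies to categorical rasters")
    pos = _coords(locales)
    codes = sorted(int(v) for v in np.unique(raster.grid) if v != raster.nodata)
    rows = []
    for a, b in _edge_pairs(graph_or_pairs):
        base = dict(locale_a=a, locale_b=b)
        try:
            t = extract_transect(raster, pos[a], pos[b])
            base["n_pixels"] = t.values.size
            base["missing"] = False
            for code in codes:
                base[f"class_{code}"] = float(np.mean(t.values == code))
        except DegenerateInputError:
            warnings.warn(f"edge ({a},{b}) entirely nodata; flagged missing")
            base["n_pixels"] = 0
            base["missing"] = True
            for code in codes:
                base[f"class_{code}"] = np.nan
        rows.append(base)
    return pd.DataFrame(rows)


def aggregate_statistic(summary: pd.DataFrame, statistic: str) -> float:
    """Aggregate a per-edge summary over edges (mean of per-edge values).

    ``statistic`` is ``mean``, ``variance``, or ``category:<code>``.
    Missing (all-nodata) edges are excluded.
    """
    ok = summary[~summary["missing"]]
    if ok.empty:
        raise DegenerateInputError("no usable edges to aggregate")
    if statistic in ("mean", "variance"):
        return float(ok[statistic].mean())
    if statistic.startswith("category:"):
        col = f"class_{int(statistic.split(':', 1)[1])}"
        if col not in ok.columns:
            raise KeyError(f"class code not present in raster: {statistic}")
        return float(ok[col].mean())
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# landscape permutation test
# ---------------------------------------------------------------------------


def landscape_permutation_test(
    graph: nx.Graph,
    raster: RasterLayer,
    locales: pd.DataFrame,
    statistic: str = "mean",
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "two-sided",
) -> PermutationResult:
    """Do the popgraph's edges sit on unusual landscape values?

    Null replicates rewire the graph by degree-preserving double-edge swaps
    with node positions fixed, re-overlay the rewired edges on the raster,
    and recompute the aggregate ``statistic`` (mean of per-edge means,
    mean of per-edge variances, or mean per-edge class proportion for
    ``category:<code>``).  p-value by the add-one rule, two-sided default.

    Transect summaries are computed once per locale pair and cached, so the
    rewired replicates only re-aggregate.
    """
    if graph.number_of_edges() < 2:
        raise DegenerateInputError("landscape test needs a graph with ≥2 edges")
    if statistic.startswith("category:"):
        code = int(statistic.split(":", 1)[1])
        if raster.kind != "categorical":
            raise ValueError("category statistic needs a categorical raster")
        if raster.class_table and code not in raster.class_table:
            raise KeyError(f"class code {code} not in raster class table")
        summarize = lambda pairs: categorical_edge_profile(raster, pairs, locales)
    else:
        summarize = lambda pairs: edge_resistance_summary(raster, pairs, locales)

    nodes = sorted(graph.nodes, key=str)
    all_pairs = [
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cache_df = summarize(all_pairs)
    col = (
        f"class_{int(statistic.split(':', 1)[1])}"
        if statistic.startswith("category:")
        else statistic
    )
    if col not in cache_df.columns:
        raise KeyError(f"statistic column {col!r} unavailable for this raster")
    pair_value = {
        (r["locale_a"], r["locale_b"]): float(r[col])
        for _, r in cache_df.iterrows()
        if not r["missing"]
    }

    def agg(edges) -> float:
        vals = [
            pair_value[k]
            for e in edges
            if (k := tuple(sorted(map(str, e)))) in pair_value
        ]
        if not vals:
            raise DegenerateInputError("no usable edges to aggregate")
        return float(np.mean(vals))

    observed = agg(graph.edges())
    rng = spawn_rng(seed, 2)
    nulls = np.empty(n_perm)
    for r in range(n_perm):
        g0 = degree_preserving_null(graph, rng)
        nulls[r] = agg(g0.edges())
    return PermutationResult.from_null(
        observed, nulls, tail=tail, seed=seed, null_model="degree_preserving"
    )
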