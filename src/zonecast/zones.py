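"""School management zones and density-stratified non-overlapping zones.

A management zone is a fixed-distance buffer (default 400 m) around a school
site boundary, within which new hot-food outlets can be refused planning
permission. Where zones overlap, outlets would be double counted, so the
merged zones are re-cut into mutually exclusive polygons stratified by outlet
density: a quartic-kernel density surface (including context points up to
2 km beyond the study boundary) is classified into three natural-breaks
classes, each school's zone takes the class of its site's interior point,
same-class zones are dissolved together, and residual overlaps between
classes are split by nearest-exclusive-region allocation (the "centre line"
rule: every point of an overlap goes to the class whose non-shared territory
is closest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from numba import njit
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

__all__ = [
    "ManagementZone",
    "DensitySurface",
    "DissolvedZone",
    "build_zones",
    "clip_and_dedupe",
    "count_in_zones",
    "kde_surface",
    "natural_breaks",
    "classify_and_dissolve",
    "split_overlaps",
    "assign_counts",
]

CLASS_LABELS = ("low", "mid", "high")


@dataclass
class ManagementZone:
    school_id: str
    geometry: Polygon
    buffer_distance: float

    def __post_init__(self):
        if not self.geometry.is_valid:
            raise ValueError(f"zone geometry invalid for {self.school_id}")
        if self.buffer_distance < 0:
            raise ValueError("buffer_distance must be non-negative")


@dataclass
class DensitySurface:
    """Gridded kernel density (outlets per square metre).

    ``values[iy, ix]`` is the density at the centre of the cell whose
    lower-left corner is ``origin + (ix, iy) * cell_size``.
    """

    origin: tuple
    cell_size: float
    bandwidth: float
    values: np.ndarray

    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell_size**2)

    def value_at(self, x: float, y: float) -> float:
        ix = int((x - self.origin[0]) // self.cell_size)
        iy = int((y - self.origin[1]) // self.cell_size)
        ny, nx = self.values.shape
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise ValueError(f"point ({x}, {y}) falls outside the density grid")
        return float(self.values[iy, ix])


@dataclass
class DissolvedZone:
    class_label: str
    geometry: Polygon
    area_k: float = field(default=None)
    count_k: float = None

    def __post_init__(self):
        if self.area_k is None:
            self.area_k = float(self.geometry.area)


def build_zones(schools: dict, distance: float = 400.0) -> list:
    """Buffer each school site boundary outward by ``distance`` metres."""
    zones = []
    for school_id, geom in schools.items():
        if geom is None or geom.is_empty:
            raise ValueError(f"empty school geometry: {school_id}")
        if not geom.is_valid:
            raise ValueError(f"invalid school geometry: {school_id}")
        zones.append(ManagementZone(school_id, geom.buffer(distance, quad_segs=32), distance))
    return zones


def clip_and_dedupe(zones: list, boundary) -> shapely.Geometry:
    """Union all zones (removing double counting) and clip to the boundary."""
    union = unary_union([z.geometry for z in zones])
    clipped = union.intersection(boundary)
    if clipped.is_empty:
        warnings.warn("management zones do not intersect the boundary")
    return clipped


def count_in_zones(points, geometry) -> int:
    """Number of points inside or on the boundary of ``geometry``.

    ``points`` is an (n, 2) array of coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return 0
    geoms = shapely.points(pts)
    return int(shapely.intersects(geoms, geometry).sum())


def kde_surface(
    points,
    cell_size: float,
    bandwidth: float,
    boundary,
    context: float = 2000.0,
) -> DensitySurface:
    """Quartic (biweight) kernel density surface of outlet points.

    Each point contributes a kernel integrating to one:
    ``K(r) = 3 / (pi h^2) * (1 - r^2/h^2)^2`` for ``r < h``. Points farther
    than ``context`` metres from the boundary are excluded (they belong to
    areas too remote to distort densities near the edge); everything closer,
    including points outside the boundary, contributes.
    """
    if not bandwidth > cell_size > 0:
        raise ValueError("require bandwidth > cell_size > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0]:
        dist = shapely.distance(shapely.points(pts), boundary)
        pts = pts[dist <= context]

    minx, miny, maxx, maxy = boundary.bounds
    pad = context + bandwidth
    x0, y0 = minx - pad, miny - pad
    nx = int(np.ceil((maxx + pad - x0) / cell_size))
    ny = int(np.ceil((maxy + pad - y0) / cell_size))
    values = np.zeros((ny, nx))
    if pts.shape[0] == 0:
        warnings.warn("no points within reach of the boundary; zero density surface")
        return DensitySurface((x0, y0), cell_size, bandwidth, values)

    cx = x0 + (np.arange(nx) + 0.5) * cell_size
    cy = y0 + (np.arange(ny) + 0.5) * cell_size
    h2 = bandwidth**2
    norm = 3.0 / (np.pi * h2)
    reach = int(np.ceil(bandwidth / cell_size)) + 1
    for px, py in pts:
        ix = int((px - x0) / cell_size)
        iy = int((py - y0) / cell_size)
        xs = slice(max(ix - reach, 0), min(ix + reach + 1, nx))
        ys = slice(max(iy - reach, 0), min(iy + reach + 1, ny))
        dx = cx[xs] - px
        dy = cy[ys] - py
        r2 = dx[None, :] ** 2 + dy[:, None] ** 2
        u = 1.0 - r2 / h2
        np.maximum(u, 0.0, out=u)
        values[ys, xs] += norm * u * u
    return DensitySurface((x0, y0), cell_size, bandwidth, values)


@njit(cache=True)
def _jenks_dp(v, k):  # pragma: no cover - numba
    """Fisher-Jenks optimal 1-D partition into k classes (values sorted)."""
    n = v.shape[0]
    cs = np.zeros(n + 1)
    cs2 = np.zeros(n + 1)
    for i in range(n):
        cs[i + 1] = cs[i] + v[i]
        cs2[i + 1] = cs2[i] + v[i] * v[i]
    # cost of segment [i, j] inclusive (0-based)
    INF = 1e300
    D = np.full((k, n), INF)
    B = np.zeros((k, n), dtype=np.int64)
    for j in range(n):
        s = cs[j + 1]
        s2 = cs2[j + 1]
        D[0, j] = s2 - s * s / (j + 1)
    for c in range(1, k):
        for j in range(c, n):
            best = INF
            arg = c
            for i in range(c, j + 1):
                seg = (cs2[j + 1] - cs2[i]) - (cs[j + 1] - cs[i]) ** 2 / (j + 1 - i)
                cost = D[c - 1, i - 1] + seg
                if cost < best:
                    best = cost
                    arg = i
            D[c, j] = best
            B[c, j] = arg
    # backtrack: first index of each of classes 1..k-1
    starts = np.zeros(k, dtype=np.int64)
    j = n - 1
    for c in range(k - 1, 0, -1):
        starts[c] = B[c, j]
        j = B[c, j] - 1
    return D[k - 1, n - 1], starts


def natural_breaks(values, k: int = 3) -> np.ndarray:
    """Optimal natural-breaks thresholds (Fisher-Jenks).

    Returns the k-1 ascending class boundaries that minimise the total
    within-class sum of squared deviations; a value equal to a threshold
    belongs to the lower class. Thresholds are the maxima of the lower
    classes.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.empty(0)
    if np.unique(v).size < k:
        raise ValueError(f"need at least {k} distinct values, got {np.unique(v).size}")
    _, starts = _jenks_dp(v, k)
    return np.array([v[starts[c] - 1] for c in range(1, k)])


def classify_values(values, thresholds) -> np.ndarray:
    """Class index per value: number of thresholds strictly below the value."""
    return np.searchsorted(np.asarray(thresholds), np.asarray(values), side="left")


def classify_and_dissolve(
    zones: list,
    surface: DensitySurface,
    boundary,
    thresholds=None,
    schools: dict = None,
) -> list:
    """Label each zone by the density class at its school's interior point,
    dissolve same-class zones, and clip to the boundary.

    The representative interior point of the school polygon (guaranteed
    inside, unlike the centroid of a concave site) indexes the surface; ties
    at a threshold fall to the lower class. ``schools`` maps school_id to the
    site polygon; if omitted, the zone geometry's own interior point is used.
    """
    if thresholds is None:
        k = len(CLASS_LABELS)
        thresholds = natural_breaks(surface.values.ravel(), k)
    by_class: dict = {}
    for z in zones:
        site = schools[z.school_id] if schools else z.geometry
        rp = site.representative_point()
        try:
            dens = surface.value_at(rp.x, rp.y)
        except ValueError as err:
            raise ValueError(f"school {z.school_id} centre off the density grid") from err
        cls = int(classify_values([dens], thresholds)[0])
        by_class.setdefault(cls, []).append(z.geometry)
    out = []
    for cls in sorted(by_class):
        geom = unary_union(by_class[cls]).intersection(boundary)
        if geom.is_empty:
            continue
        label = CLASS_LABELS[cls] if cls < len(CLASS_LABELS) else f"class_{cls}"
        out.append(DissolvedZone(label, geom))
    return out


def split_overlaps(dissolved: list, cell: float = 10.0) -> list:
    """Allocate overlaps between dissolved zones by nearest exclusive region.

    The shared region is rasterised at ``cell`` metres; every cell goes to the
    class whose exclusive (non-shared) territory is nearest its centre, ties
    to the lower class in the input order. A zone wholly inside other zones
    has no exclusive territory; it keeps its full geometry (the enclosing
    zones lose the hole) — a density island should not be absorbed by its
    surroundings. Union is preserved up to the cell approximation of the
    shared-region boundary.
    """
    if not dissolved:
        raise ValueError("no zones to split")
    geoms = [z.geometry for z in dissolved]
    union = unary_union(geoms)
    exclusive = []
    for i, g in enumerate(geoms):
        others = unary_union([geoms[j] for j in range(len(geoms)) if j != i])
        exclusive.append(g.difference(others))
    # zones with no territory of their own claim their full geometry up front
    claimed = []
    for i, g in enumerate(geoms):
        if exclusive[i].is_empty or exclusive[i].area < 1e-9:
            keep = g.difference(unary_union(claimed)) if claimed else g
            exclusive[i] = keep
            claimed.append(keep)
    shared = union.difference(unary_union(exclusive))
    if shared.is_empty or shared.area < 1e-9:
        return [
            DissolvedZone(z.class_label, ex, count_k=z.count_k)
            for z, ex in zip(dissolved, exclusive)
            if not ex.is_empty
        ]

    minx, miny, maxx, maxy = shared.bounds
    nx = int(np.ceil((maxx - minx) / cell))
    ny = int(np.ceil((maxy - miny) / cell))
    xs = minx + (np.arange(nx) + 0.5) * cell
    ys = miny + (np.arange(ny) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys)
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    pts = shapely.points(centres)
    shapely.prepare(shared)
    # keep every cell whose square can touch the shared region (centre within
    # half a diagonal); squares are clipped back to it, so no area leaks out
    near = shapely.dwithin(pts, shared, cell * 0.7072)
    pts = pts[near]
    centres = centres[near]
    if centres.shape[0] == 0:
        return [DissolvedZone(z.class_label, z.geometry, count_k=z.count_k) for z in dissolved]

    dists = np.column_stack(
        [
            shapely.distance(pts, ex) if not ex.is_empty else np.full(len(pts), np.inf)
            for ex in exclusive
        ]
    )
    owner = np.argmin(dists, axis=1)  # argmin takes the first (lower) on ties

    out = []
    for i, z in enumerate(dissolved):
        cells = centres[owner == i]
        if cells.shape[0]:
            squares = [
                box(cxx - cell / 2, cyy - cell / 2, cxx + cell / 2, cyy + cell / 2)
                for cxx, cyy in cells
            ]
            patch = unary_union(squares).intersection(shared)
            geom = unary_union([exclusive[i], patch])
        else:
            geom = exclusive[i]
        if geom.is_empty:
            continue
        out.append(DissolvedZone(z.class_label, geom, count_k=z.count_k))
    return out


def assign_counts(dissolved: list, points) -> list:
    """Attach outlet counts to zones from a point snapshot."""
    return [
        DissolvedZone(z.class_label, z.geometry, count_k=float(count_in_zones(points, z.geometry)))
        for z in dissolved
    ]
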