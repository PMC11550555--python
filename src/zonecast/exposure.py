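"""Population exposure to outlets within management zones.

Exposure is assessed over three domains per commuting sub-population: a
1-mile disc around the home OA centroid, the same around the workplace
centroid, and a buffered shortest street-network route between them (500 m
for automobile modes, 100 m for active travel; public-transport users are
exposed only on buffered walks to and from their nearest transit stop — no
exposure accrues on board). People working from home, or living and working
in the same OA, have no route and their home-domain exposure is counted
twice. For a zone k with outlet count count_k and area area_k, a
sub-population of size population overlapping fraction a of the zone in
domain p contributes

    exposure = population * count_k * a        (a = area_intersected / area_k)

and the per-capita figure divides the grand total over (i, j, m, k, p) by the
total commuting population.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .config import MODES, RadiiConfig
from .growth import GrowthSchedule
from .zones import DissolvedZone

__all__ = [
    "CommuteFlow",
    "ExposureSpace",
    "ExposureTerm",
    "ExposureSummary",
    "split_modes",
    "domain_buffers",
    "exposure_term",
    "compute_terms",
    "total_exposure",
    "exposure_by_domain",
    "project_exposure",
    "shortest_path",
    "nearest_node",
]

AUTOMOBILE_MODES = {"car_van", "motorcycle"}
ACTIVE_MODES = {"bicycle", "on_foot"}
PUBLIC_MODES = {"tram_underground", "bus"}
DOMAINS = ("home", "work", "route")


@dataclass
class CommuteFlow:
    origin_oa: str
    dest_oa: str
    mode: str
    population: float

    def __post_init__(self):
        if self.population < 0:
            raise ValueError("population must be non-negative")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode}")


@dataclass
class ExposureSpace:
    origin_oa: str
    dest_oa: str
    mode: str
    home: object  # Polygon
    work: object  # Polygon
    route: Optional[object] = None  # Polygon or None
    double_home: bool = False
    route_excluded: bool = False  # endpoint unreachable on the network

    def domain_geometry(self, domain: str):
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain}")
        return getattr(self, domain)


@dataclass
class ExposureTerm:
    origin_oa: str
    dest_oa: str
    mode: str
    zone_label: str
    domain: str
    area_intersected: float
    value: float


@dataclass
class ExposureSummary:
    exposure_total: float
    population_total: float

    @property
    def exposure_per_capita(self) -> float:
        return self.exposure_total / self.population_total


def split_modes(flows: pd.DataFrame, lsoa_shares: pd.DataFrame, oa_to_lsoa: dict) -> list:
    """Split raw OA-pair flows by the origin OA's parent-LSOA mode shares.

    Fractional counts are retained; modes with zero share are dropped (they
    carry no population). Unmapped origin OAs are rejected by name.
    """
    out = []
    for row in flows.itertuples(index=False):
        if row.origin_oa not in oa_to_lsoa:
            raise KeyError(f"origin OA {row.origin_oa} has no LSOA parent")
        lsoa = oa_to_lsoa[row.origin_oa]
        if lsoa not in lsoa_shares.index:
            raise KeyError(f"LSOA {lsoa} missing from mode-share table")
        shares = lsoa_shares.loc[lsoa]
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError(f"mode shares for {lsoa} do not sum to 1")
        for mode in lsoa_shares.columns:
            pop = float(row.count * shares[mode])
            if pop > 0:
                out.append(CommuteFlow(row.origin_oa, row.dest_oa, mode, pop))
    return out


def shortest_path(graph, source, target=None):
    """Dijkstra over edge ``length`` with lexicographic node tie-breaking.

    With ``target=None`` returns the full distance map (for nearest-stop
    queries); otherwise returns ``(distance, node_path)`` or ``(inf, None)``
    when unreachable. Using (distance, node) heap keys makes tie resolution
    independent of insertion order, hence reproducible.
    """
    dist = {source: 0.0}
    prev = {}
    heap = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if target is not None and u == target:
            break
        for v in sorted(graph.neighbors(u)):
            nd = d + graph.edges[u, v]["length"]
            if nd < dist.get(v, np.inf) - 1e-12:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    if target is None:
        return dist
    if target not in dist:
        return np.inf, None
    path = [target]
    while path[-1] != source:
        path.append(prev[path[-1]])
    return dist[target], path[::-1]


def nearest_node(graph, x: float, y: float):
    """Network node nearest to (x, y) in the plane; ties to the lower id."""
    best = None
    for n in sorted(graph.nodes):
        d = (graph.nodes[n]["x"] - x) ** 2 + (graph.nodes[n]["y"] - y) ** 2
        if best is None or d < best[0] - 1e-12:
            best = (d, n)
    return best[1]


def _path_geometry(graph, path):
    coords = [(graph.nodes[n]["x"], graph.nodes[n]["y"]) for n in path]
    if len(coords) < 2:
        return Point(coords[0])
    return LineString(coords)


def _nearest_stop_path(graph, node, stops):
    """Network-nearest stop from ``node``; ties broken by stop id order."""
    dist = shortest_path(graph, node)
    best = None
    for s in sorted(stops):
        d = dist.get(s, np.inf)
        if best is None or d < best[0] - 1e-12:
            best = (d, s)
    if best is None or not np.isfinite(best[0]):
        return None
    _, path = shortest_path(graph, node, best[1])
    return path


def domain_buffers(
    flow: CommuteFlow,
    centroids: dict,
    network,
    stops,
    radii: RadiiConfig = None,
    _cache: dict = None,
) -> ExposureSpace:
    """Build the home/work/route exposure space for one mode-specific flow.

    ``centroids`` maps oa_id -> (x, y) population-weighted centroid. An
    optional ``_cache`` dict (shared across calls) memoises node snapping,
    shortest paths and buffered geometries — the synthetic pipeline evaluates
    thousands of flows over the same small lattice.
    """
    radii = radii or RadiiConfig()
    cache = _cache if _cache is not None else {}
    for oa in (flow.origin_oa, flow.dest_oa):
        if oa not in centroids:
            raise KeyError(f"no centroid for OA {oa}")

    def disc(oa):
        key = ("disc", oa)
        if key not in cache:
            cache[key] = Point(*centroids[oa]).buffer(radii.home_work, quad_segs=32)
        return cache[key]

    home, work = disc(flow.origin_oa), disc(flow.dest_oa)
    same_place = flow.origin_oa == flow.dest_oa or flow.mode == "work_from_home"
    if same_place:
        return ExposureSpace(flow.origin_oa, flow.dest_oa, flow.mode, home, work, None, double_home=True)

    def snap(oa):
        key = ("node", oa)
        if key not in cache:
            cache[key] = nearest_node(network, *centroids[oa])
        return cache[key]

    n_home, n_work = snap(flow.origin_oa), snap(flow.dest_oa)

    def buffered_path(src, dst, radius):
        key = ("path", src, dst, radius)
        if key not in cache:
            d, path = shortest_path(network, src, dst)
            if path is None:
                cache[key] = None
            else:
                cache[key] = _path_geometry(network, path).buffer(radius, quad_segs=32)
        return cache[key]

    if flow.mode in AUTOMOBILE_MODES or flow.mode in ACTIVE_MODES:
        radius = radii.automobile if flow.mode in AUTOMOBILE_MODES else radii.active
        route = buffered_path(n_home, n_work, radius)
        if route is None:
            warnings.warn(f"no network route {flow.origin_oa} -> {flow.dest_oa}; route domain dropped")
            return ExposureSpace(flow.origin_oa, flow.dest_oa, flow.mode, home, work, None, route_excluded=True)
        return ExposureSpace(flow.origin_oa, flow.dest_oa, flow.mode, home, work, route)

    # public transport: buffered ingress and egress walks, nothing on board
    def access_leg(node):
        key = ("access", node)
        if key not in cache:
            path = _nearest_stop_path(network, node, stops)
            cache[key] = None if path is None else _path_geometry(network, path).buffer(
                radii.ingress, quad_segs=32
            )
        return cache[key]

    ingress, egress = access_leg(n_home), access_leg(n_work)
    if ingress is None or egress is None:
        warnings.warn(f"no transit access for {flow.origin_oa} -> {flow.dest_oa}; route domain dropped")
        return ExposureSpace(flow.origin_oa, flow.dest_oa, flow.mode, home, work, None, route_excluded=True)
    return ExposureSpace(flow.origin_oa, flow.dest_oa, flow.mode, home, work, ingress.union(egress))


def exposure_term(space: ExposureSpace, population: float, zone: DissolvedZone, domain: str) -> ExposureTerm:
    """One exposure contribution: population x count_k x overlap fraction.

    The home-domain term is doubled for same-OA and work-from-home flows.
    """
    if zone.area_k <= 0:
        raise ValueError("zone has zero area")
    geom = space.domain_geometry(domain)
    if geom is None:
        area = 0.0
    else:
        area = float(geom.intersection(zone.geometry).area)
    value = population * zone.count_k * area / zone.area_k
    if domain == "home" and space.double_home:
        value *= 2.0
    return ExposureTerm(space.origin_oa, space.dest_oa, space.mode, zone.class_label, domain, area, value)


def compute_terms(spaces_with_pop, zones: list) -> list:
    """All ExposureTerms for (space, population) pairs over zones and domains."""
    terms = []
    for space, pop in spaces_with_pop:
        for zone in zones:
            for domain in DOMAINS:
                terms.append(exposure_term(space, pop, zone, domain))
    return terms


def total_exposure(terms: list, flows: list) -> ExposureSummary:
    """Sum exposure over all indices; population from the mode-split flows."""
    population = float(sum(f.population for f in flows))
    if population <= 0:
        raise ValueError("total population must be positive")
    return ExposureSummary(float(sum(t.value for t in terms)), population)


def exposure_by_domain(terms: list) -> dict:
    """Shares of total exposure by domain (home, work, route); sums to 1."""
    totals = {d: 0.0 for d in DOMAINS}
    for t in terms:
        totals[t.domain] += t.value
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total exposure is zero")
    return {d: totals[d] / grand for d in DOMAINS}


def project_exposure(summary_baseline: ExposureSummary, schedule: GrowthSchedule) -> pd.DataFrame:
    """Per-year per-capita exposure: baseline scaled by (1 + growth rate).

    Exposure is linear in every zone's outlet count, and growth scales all
    counts by the same factor with geometry fixed, so per-capita exposure
    scales by exactly the same multiplier (estimate and bounds alike).
    """
    base = summary_baseline.exposure_per_capita
    r = schedule.rates
    return pd.DataFrame(
        {
            "year": r["year"],
            "per_capita_est": base * (1.0 + r["rate_est"]),
            "per_capita_lo95": base * (1.0 + r["rate_lo95"]),
            "per_capita_hi95": base * (1.0 + r["rate_hi95"]),
        }
    )
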