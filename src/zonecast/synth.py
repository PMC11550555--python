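"""Synthetic study-area generator.

Produces every layer the pipeline consumes — administrative boundary, school
site polygons, a lattice street network, output-area (OA) centroids nested in
larger mode-share zones (LSOAs), transit stops, quarterly outlet snapshots
and an origin-destination commuter flow table — with known ground-truth
parameters so recovery can be tested end to end.

All randomness flows from ``config.seed`` through independent
``numpy.random.default_rng`` streams per layer, so regenerating with the same
config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .config import SyntheticConfig

__all__ = ["RegionBundle", "generate_region", "generate_outlet_history", "generate_commute_flows"]


@dataclass
class RegionBundle:
    """In-memory bundle of the static synthetic layers."""

    boundary: Polygon
    schools: dict  # school_id -> Polygon
    network: nx.Graph  # nodes carry x, y; edges carry length
    oa_centroids: pd.DataFrame  # oa_id, x, y, node, lsoa_id
    stops: list  # node ids with transit access
    attractors: np.ndarray  # (n, 2) cluster centres of the outlet process


def _lattice(region_size: float, spacing: float) -> nx.Graph:
    n_side = int(round(region_size / spacing)) + 1
    g = nx.Graph()
    for i in range(n_side):
        for j in range(n_side):
            g.add_node(i * n_side + j, x=j * spacing, y=i * spacing)
    for i in range(n_side):
        for j in range(n_side):
            nid = i * n_side + j
            if j + 1 < n_side:
                g.add_edge(nid, nid + 1, length=spacing)
            if i + 1 < n_side:
                g.add_edge(nid, nid + n_side, length=spacing)
    return g


def generate_region(config: SyntheticConfig) -> RegionBundle:
    """Generate boundary, schools, street lattice, OA centroids and stops."""
    L = config.region_size
    rng = np.random.default_rng([int(config.seed), 0])
    boundary = box(0.0, 0.0, L, L)

    attractors = rng.uniform(0.15 * L, 0.85 * L, size=(config.n_attractors, 2))

    # disjoint square school sites; roughly half pulled toward attractors so
    # the density classification has contrast
    s = config.school_size
    schools: dict = {}
    placed: list = []
    attempts = 0
    while len(schools) < config.n_schools:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place disjoint school sites; lower n_schools")
        k = len(schools)
        if k % 2 == 0 and config.n_attractors > 0:
            centre = attractors[k // 2 % config.n_attractors] + rng.normal(0, 2 * s, 2)
        else:
            centre = rng.uniform(2 * s, L - 2 * s, 2)
        cx, cy = centre
        if not (s < cx < L - s and s < cy < L - s):
            continue
        poly = box(cx - s / 2, cy - s / 2, cx + s / 2, cy + s / 2)
        if any(poly.distance(other) < s for other in placed):
            continue
        placed.append(poly)
        schools[f"school_{k:03d}"] = poly

    network = _lattice(L, config.grid_spacing)
    node_ids = np.array(sorted(network.nodes))
    chosen = np.sort(rng.choice(node_ids, size=config.n_oa, replace=False))
    xs = np.array([network.nodes[n]["x"] for n in chosen])
    ys = np.array([network.nodes[n]["y"] for n in chosen])
    # spatially coherent LSOA parents: order OAs by row-major position, chunk
    order = np.lexsort((xs, ys))
    lsoa = np.empty(config.n_oa, dtype=int)
    bounds_idx = np.array_split(np.arange(config.n_oa), config.n_lsoa)
    for li, idx in enumerate(bounds_idx):
        lsoa[order[idx]] = li
    oa = pd.DataFrame(
        {
            "oa_id": [f"oa_{i:04d}" for i in range(config.n_oa)],
            "x": xs,
            "y": ys,
            "node": chosen,
            "lsoa_id": [f"lsoa_{l:03d}" for l in lsoa],
        }
    )
    remaining = np.setdiff1d(node_ids, chosen)
    pool = remaining if remaining.size >= config.n_stops else node_ids
    stops = sorted(rng.choice(pool, size=min(config.n_stops, pool.size), replace=False).tolist())
    return RegionBundle(boundary, schools, network, oa, stops, attractors)


def generate_outlet_history(config: SyntheticConfig, region: RegionBundle) -> pd.DataFrame:
    """Quarterly outlet point snapshots with a linear-drift-plus-noise count.

    The point process is cumulative: outlets persist across quarters; when the
    noisy target count falls, the most recently opened outlets are removed
    first. Placement mixes Gaussian clusters around the region's attractor
    points (fraction ``attractor_fraction``) with a uniform background.

    Returns a DataFrame with columns ``x, y, quarter, label`` where ``quarter``
    is the 0-based quarter index and ``label`` the ISO year-quarter.
    """
    if config.n_quarters < 3:
        raise ValueError("n_quarters must be at least 3 for any modelling")
    rng = np.random.default_rng([int(config.seed), 1])
    L = config.region_size
    attractors = region.attractors

    def sample_points(n):
        out = np.empty((0, 2))
        while out.shape[0] < n:
            m = n - out.shape[0]
            use_attr = rng.random(m) < config.attractor_fraction
            cand = rng.uniform(0, L, (m, 2))
            n_attr = int(use_attr.sum())
            if n_attr and attractors.shape[0]:
                which = rng.integers(0, attractors.shape[0], n_attr)
                cand[use_attr] = attractors[which] + rng.normal(0, config.attractor_sd, (n_attr, 2))
            inside = (
                (cand[:, 0] >= 0) & (cand[:, 0] <= L) & (cand[:, 1] >= 0) & (cand[:, 1] <= L)
            )
            out = np.vstack([out, cand[inside]])
        return out[:n]

    noise = rng.normal(0.0, config.noise_sd, config.n_quarters) if config.noise_sd > 0 else np.zeros(config.n_quarters)
    start = pd.Period(config.start_quarter, freq="Q")
    points = sample_points(0)
    rows = []
    for t in range(config.n_quarters):
        target = int(round(max(0.0, config.n_outlets_baseline + config.quarterly_drift * t + noise[t])))
        if target > points.shape[0]:
            points = np.vstack([points, sample_points(target - points.shape[0])])
        elif target < points.shape[0]:
            points = points[:target]
        label = str(start + t)
        rows.append(
            pd.DataFrame(
                {"x": points[:, 0], "y": points[:, 1], "quarter": t, "label": label}
            )
        )
    return pd.concat(rows, ignore_index=True)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (exact sum)."""
    w = weights / weights.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        rema = raw - base
        # deterministic tie-break: larger remainder first, then lower index
        order = np.lexsort((np.arange(rema.size), -rema))
        base[order[:short]] += 1
    return base


def generate_commute_flows(config: SyntheticConfig, region: RegionBundle):
    """Gravity-style OA-pair commuter flows plus the LSOA mode-share table.

    Each origin's configured workforce is allocated across destinations with
    weight exp(-d_ij / gravity_scale) (distance decay; the origin itself gets
    the largest weight, so same-OA workers always exist) using largest-
    remainder rounding, which keeps row sums exactly equal to the workforce.
    """
    oa = region.oa_centroids
    xy = oa[["x", "y"]].to_numpy()
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    weights = np.exp(-d / config.gravity_scale)
    rows = []
    for i in range(len(oa)):
        alloc = _largest_remainder(weights[i], config.workers_per_oa)
        for j in np.nonzero(alloc)[0]:
            rows.append((oa.oa_id.iloc[i], oa.oa_id.iloc[j], int(alloc[j])))
    flows = pd.DataFrame(rows, columns=["origin_oa", "dest_oa", "count"])

    lsoas = sorted(oa.lsoa_id.unique())
    shares = pd.DataFrame(
        {mode: [share] * len(lsoas) for mode, share in config.mode_shares.items()},
        index=pd.Index(lsoas, name="lsoa_id"),
    )
    return flows, shares
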