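"""Plain-text readers and writers for every layer the pipeline touches.

GeoJSON for vector layers (via shapely's geo-interface), ESRI ASCII grid for
the density surface, CSV for tabular layers. All writers are deterministic
(sorted keys, fixed float formatting) so reruns are byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

__all__ = [
    "write_geojson",
    "read_geojson",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_series_csv",
    "read_series_csv",
    "write_network_csv",
    "read_network_csv",
    "check_crs_consistent",
]


def write_geojson(path, features, crs: str = None):
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props or {}}
            for geom, props in features
        ],
    }
    if crs:
        fc["crs"] = {"type": "name", "properties": {"name": crs}}
    Path(path).write_text(json.dumps(fc, sort_keys=True, allow_nan=False) + "\n")


def read_geojson(path):
    """Read a GeoJSON FeatureCollection; returns (features, crs_name)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: malformed GeoJSON at line {err.lineno}") from err
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection")
    feats = []
    for i, f in enumerate(doc.get("features", [])):
        try:
            feats.append((shape(f["geometry"]), f.get("properties") or {}))
        except Exception as err:
            raise ValueError(f"{path}: bad geometry in feature {i}") from err
    crs = None
    if "crs" in doc:
        crs = doc["crs"].get("properties", {}).get("name")
    return feats, crs


def check_crs_consistent(crs_list):
    """Reject inputs whose declared CRS metadata disagree."""
    named = {c for c in crs_list if c}
    if len(named) > 1:
        raise ValueError(f"mixed CRS among input layers: {sorted(named)}")


def write_ascii_grid(path, surface):
    """Write a DensitySurface as an ESRI ASCII grid (row 0 = north)."""
    v = surface.values
    header = (
        f"ncols {v.shape[1]}\n"
        f"nrows {v.shape[0]}\n"
        f"xllcorner {surface.origin[0]:.6f}\n"
        f"yllcorner {surface.origin[1]:.6f}\n"
        f"cellsize {surface.cell_size:.6f}\n"
        f"NODATA_value -9999\n"
    )
    body = "\n".join(" ".join(f"{x:.10e}" for x in row) for row in v[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (values, origin, cell_size)."""
    lines = Path(path).read_text().splitlines()
    hdr = {}
    for i, line in enumerate(lines[:6]):
        key, val = line.split()
        hdr[key.lower()] = float(val)
    values = np.loadtxt(lines[6:])[::-1]
    return values, (hdr["xllcorner"], hdr["yllcorner"]), hdr["cellsize"]


def write_series_csv(path, series):
    """quarter label, count, imputed flag."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["quarter", "count", "imputed"])
        for q, v, m in zip(series.quarters, series.values, series.missing_mask):
            w.writerow([str(q), repr(float(v)), int(m)])


def read_series_csv(path):
    from .forecasting import QuarterlySeries

    df = pd.read_csv(path)
    for col in ("quarter", "count", "imputed"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return QuarterlySeries(df["quarter"].iloc[0], df["count"].to_numpy(), df["imputed"].astype(bool).to_numpy())


def write_network_csv(path, graph):
    """Edge list with node coordinates: u, v, xu, yu, xv, yv, length."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["u", "v", "xu", "yu", "xv", "yv", "length"])
        for u, v in sorted(graph.edges):
            nu, nv = graph.nodes[u], graph.nodes[v]
            w.writerow([u, v, repr(nu["x"]), repr(nu["y"]), repr(nv["x"]), repr(nv["y"]), repr(graph.edges[u, v]["length"])])


def read_network_csv(path):
    df = pd.read_csv(path)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_node(int(row.u), x=float(row.xu), y=float(row.yu))
        g.add_node(int(row.v), x=float(row.xv), y=float(row.yv))
        g.add_edge(int(row.u), int(row.v), length=float(row.length))
    return g
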