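"""End-to-end pipeline driver: zones -> series -> model -> growth -> exposure.

Each stage writes a plain-text artifact into the run directory and a manifest
records the configuration hash, the seed, and a SHA-256 per artifact, so a
rerun with the same configuration is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping

from . import exposure as expo
from . import forecasting as fc
from . import growth as gr
from . import io as zio
from . import zones as zn
from .config import PipelineConfig

__all__ = ["run_pipeline", "StageError", "write_synthetic_inputs"]

log = logging.getLogger("zonecast")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_synthetic_inputs(config, out_dir) -> dict:
    """Generate the synthetic layers and write them as pipeline input files."""
    from .synth import generate_commute_flows, generate_outlet_history, generate_region

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region = generate_region(config)
    outlets = generate_outlet_history(config, region)
    flows, shares = generate_commute_flows(config, region)

    paths = {k: out / f"{k}.{ext}" for k, ext in [
        ("boundary", "geojson"), ("schools", "geojson"), ("centroids", "geojson"),
        ("stops", "geojson"), ("network", "csv"), ("outlets", "csv"),
        ("flows", "csv"), ("mode_shares", "csv"),
    ]}
    zio.write_geojson(paths["boundary"], [(region.boundary, {"name": "study_area"})])
    zio.write_geojson(paths["schools"], [(g, {"school_id": sid}) for sid, g in sorted(region.schools.items())])
    from shapely.geometry import Point

    zio.write_geojson(
        paths["centroids"],
        [
            (Point(r.x, r.y), {"oa_id": r.oa_id, "lsoa_id": r.lsoa_id, "node": int(r.node)})
            for r in region.oa_centroids.itertuples(index=False)
        ],
    )
    zio.write_geojson(
        paths["stops"],
        [
            (Point(region.network.nodes[s]["x"], region.network.nodes[s]["y"]), {"node": int(s)})
            for s in region.stops
        ],
    )
    zio.write_network_csv(paths["network"], region.network)
    outlets.to_csv(paths["outlets"], index=False)
    flows.to_csv(paths["flows"], index=False)
    shares.to_csv(paths["mode_shares"])
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns a dict of artifact paths.

    Stage order: zones -> series -> fit/CV -> forecast -> growth -> exposure
    -> projection. Any failure aborts with the stage name; artifacts already
    written are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s", name)
                return fn()
            except Exception as err:
                raise StageError(name, err) from err
        return deco

    @stage("load")
    def layers():
        boundary_feats, crs_b = zio.read_geojson(config.boundary)
        school_feats, crs_s = zio.read_geojson(config.schools)
        centroid_feats, crs_c = zio.read_geojson(config.centroids)
        stop_feats, crs_t = zio.read_geojson(config.stops)
        zio.check_crs_consistent([crs_b, crs_s, crs_c, crs_t])
        return {
            "boundary": boundary_feats[0][0],
            "schools": {p["school_id"]: g for g, p in school_feats},
            "centroids": {p["oa_id"]: (g.x, g.y) for g, p in centroid_feats},
            "oa_to_lsoa": {p["oa_id"]: p["lsoa_id"] for _, p in centroid_feats},
            "stops": [p["node"] for _, p in stop_feats],
            "network": zio.read_network_csv(config.network),
            "outlets": pd.read_csv(config.outlets),
        }

    @stage("zones")
    def zone_union():
        zones = zn.build_zones(layers["schools"], config.buffer_distance)
        union = zn.clip_and_dedupe(zones, layers["boundary"])
        zio.write_geojson(out / "zone_union.geojson", [(union, {"n_zones": len(zones)})])
        artifacts["zone_union"] = str(out / "zone_union.geojson")
        log.info("zones: %d schools, union area %.0f m2", len(zones), union.area)
        return zones, union

    zones_list, union = zone_union

    @stage("series")
    def series():
        s = fc.build_series(layers["outlets"], union, config.known_missing)
        zio.write_series_csv(out / "series.csv", s)
        artifacts["series"] = str(out / "series.csv")
        return s

    @stage("model")
    def model_and_cv():
        model = fc.auto_arima(series, alpha=config.kpss_alpha, p_max=config.p_max, q_max=config.q_max)
        q_stat, lb_p = fc.ljung_box(model)
        report = {
            "order": list(model.order),
            "include_drift": model.include_drift,
            "constant": model.c,
            "ar_coefficients": list(map(float, model.phi)),
            "ma_coefficients": list(map(float, model.theta)),
            "sigma2": model.sigma2,
            "aicc": model.aicc,
            "boxcox_lambda": model.boxcox_lambda,
            "ljung_box_q": None if q_stat != q_stat else q_stat,
            "ljung_box_p": None if lb_p != lb_p else lb_p,
        }
        if config.run_cv:
            ev_arima = fc.rolling_origin_cv(
                series, fc.ArimaForecaster(p_max=config.p_max, q_max=config.q_max),
                min_train=config.cv_min_train, max_h=config.cv_max_h,
            )
            ev_ets = fc.ets_benchmark(series, min_train=config.cv_min_train, max_h=config.cv_max_h)
            report["cv"] = {
                "arima": {"rmse": ev_arima.rmse, "mase": ev_arima.mase, "n_forecasts": ev_arima.n_forecasts},
                "ets": {"rmse": ev_ets.rmse, "mase": ev_ets.mase, "n_forecasts": ev_ets.n_forecasts},
            }
        (out / "model.json").write_text(json.dumps(report, sort_keys=True, indent=1) + "\n")
        artifacts["model"] = str(out / "model.json")
        return model

    @stage("forecast")
    def annual():
        table = fc.forecast_annual(series, model_and_cv, config.horizon_year)
        table.to_csv(out / "forecast_annual.csv", index=False)
        artifacts["forecast_annual"] = str(out / "forecast_annual.csv")
        return table

    @stage("growth")
    def schedule():
        base_year = gr.baseline_year(config.adoption_year)
        base_period = pd.Period(f"{base_year}Q2", freq="Q")
        quarters = series.quarters
        if base_period not in quarters:
            raise ValueError(f"baseline quarter {base_period} not in the observed series")
        base_count = float(series.values[quarters.get_loc(base_period)])
        sched = gr.to_growth_schedule(annual, base_count, base_year)
        proj = gr.apply_growth(base_count, sched, area_id="study_area")
        sched.rates.to_csv(out / "growth_schedule.csv", index=False)
        proj.counts.to_csv(out / "projection_counts.csv", index=False)
        artifacts["growth_schedule"] = str(out / "growth_schedule.csv")
        artifacts["projection_counts"] = str(out / "projection_counts.csv")
        return sched, base_count, base_period

    sched, base_count, base_period = schedule

    @stage("exposure")
    def exposure_summary():
        base_year = sched.baseline_year
        outlets = layers["outlets"]
        snap = outlets.loc[outlets["label"] == str(base_period), ["x", "y"]].to_numpy()
        surface = zn.kde_surface(
            snap, config.kde_cell_size, config.kde_bandwidth, layers["boundary"], config.kde_context
        )
        zio.write_ascii_grid(out / "density.asc", surface)
        dissolved = zn.classify_and_dissolve(zones_list, surface, layers["boundary"], schools=layers["schools"])
        split = zn.split_overlaps(dissolved)
        split = zn.assign_counts(split, snap)
        zio.write_geojson(
            out / "zones_dissolved.geojson",
            [(z.geometry, {"class_label": z.class_label, "area_k": z.area_k, "count_k": z.count_k}) for z in split],
        )
        artifacts["zones_dissolved"] = str(out / "zones_dissolved.geojson")

        flows_df = pd.read_csv(config.flows)
        shares_df = pd.read_csv(config.mode_shares, index_col="lsoa_id")
        mode_flows = expo.split_modes(flows_df, shares_df, layers["oa_to_lsoa"])
        cache: dict = {}
        spaces = [
            (expo.domain_buffers(f, layers["centroids"], layers["network"], layers["stops"], config.radii, _cache=cache), f.population)
            for f in mode_flows
        ]
        zones_nonzero = [z for z in split if z.area_k > 0]
        terms = expo.compute_terms(spaces, zones_nonzero)
        summary = expo.total_exposure(terms, mode_flows)
        shares_by_domain = expo.exposure_by_domain(terms)
        pd.DataFrame([t.__dict__ for t in terms]).to_csv(out / "exposure_terms.csv", index=False)
        artifacts["exposure_terms"] = str(out / "exposure_terms.csv")
        report = {
            "baseline_year": base_year,
            "exposure_total": summary.exposure_total,
            "population_total": summary.population_total,
            "exposure_per_capita": summary.exposure_per_capita,
            "shares_by_domain": shares_by_domain,
        }
        (out / "exposure.json").write_text(json.dumps(report, sort_keys=True, indent=1) + "\n")
        artifacts["exposure"] = str(out / "exposure.json")
        return summary

    @stage("projection")
    def projection():
        table = expo.project_exposure(exposure_summary, sched)
        table.to_csv(out / "exposure_projection.csv", index=False)
        artifacts["exposure_projection"] = str(out / "exposure_projection.csv")
        return table

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "artifacts": {k: _sha256(Path(v)) for k, v in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
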