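"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

MODES = (
    "car_van",
    "motorcycle",
    "tram_underground",
    "bus",
    "bicycle",
    "on_foot",
    "work_from_home",
)

#: commute mode split used by default, loosely matching English census patterns
DEFAULT_MODE_SHARES = {
    "car_van": 0.60,
    "motorcycle": 0.01,
    "tram_underground": 0.04,
    "bus": 0.09,
    "bicycle": 0.03,
    "on_foot": 0.12,
    "work_from_home": 0.11,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study area and its input layers.

    Counts follow a linear-drift-plus-noise quarterly trend; outlets are
    placed as a mixture of Gaussian clusters around attractor points and a
    uniform background, so the density surface has genuine high/mid/low
    structure. Distances are abstract planar metres.
    """

    seed: int = 0
    region_size: float = 8000.0
    n_schools: int = 12
    n_outlets_baseline: int = 200
    quarterly_drift: float = 2.0
    noise_sd: float = 3.0
    n_quarters: int = 41
    n_oa: int = 50
    n_lsoa: int = 10
    mode_shares: dict = field(default_factory=lambda: dict(DEFAULT_MODE_SHARES))
    grid_spacing: float = 500.0
    # generator plumbing
    workers_per_oa: int = 30
    n_stops: int = 12
    n_attractors: int = 3
    attractor_fraction: float = 0.7
    attractor_sd: float = 400.0
    school_size: float = 100.0
    gravity_scale: float = 2000.0
    start_quarter: str = "2011Q2"

    def __post_init__(self):
        for name in (
            "region_size",
            "n_schools",
            "n_outlets_baseline",
            "n_quarters",
            "n_oa",
            "n_lsoa",
            "grid_spacing",
            "workers_per_oa",
            "n_stops",
            "n_attractors",
            "school_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_lsoa > self.n_oa:
            raise ValueError("n_lsoa must not exceed n_oa")
        total = sum(self.mode_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode_shares must sum to 1, got {total}")
        unknown = set(self.mode_shares) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RadiiConfig:
    """Buffer radii (metres) defining the exposure domains per travel mode."""

    home_work: float = 1609.344  # 1 mile
    automobile: float = 500.0
    active: float = 100.0
    ingress: float = 100.0


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline run needs."""

    out_dir: str
    boundary: str
    schools: str
    outlets: str
    flows: str
    mode_shares: str
    centroids: str
    network: str
    stops: str

    buffer_distance: float = 400.0
    kde_cell_size: float = 100.0
    kde_bandwidth: float = 800.0
    kde_context: float = 2000.0
    n_classes: int = 3
    p_max: int = 5
    q_max: int = 5
    kpss_alpha: float = 0.05
    run_cv: bool = True
    cv_min_train: int = 8
    cv_max_h: int = 8
    radii: RadiiConfig = field(default_factory=RadiiConfig)
    adoption_year: int = 2017
    horizon_year: int = 2031
    known_missing: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.radii, dict):
            self.radii = RadiiConfig(**self.radii)
        baseline = self.adoption_year - 2
        if self.horizon_year <= baseline:
            raise ValueError("horizon_year must be after the baseline year")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        missing = [
            p
            for key in ("boundary", "schools", "outlets", "flows", "mode_shares", "centroids", "network", "stops")
            if not Path(p := getattr(cfg, key)).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input layers: {missing}")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
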