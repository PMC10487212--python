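"""Pipeline configuration: one YAML document, per-stage derived seeds."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed so any stage is individually replayable."""
    return (root_seed * 31 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything any stage consumes, round-trippable through YAML."""

    seed: int = 0

    # design (the study scale: 6 x 10 x 10 = 600 ROIs)
    origins: int = 6
    fruit_per_origin: int = 10
    regions_per_fruit: int = 10

    # raster geometry
    raster: tuple[int, int] = (256, 256)
    mm_per_px: float = 0.5
    roi_diameter_mm: float = 18.0
    n_map_fruit: int = 2          # validation fruit rendered as full cubes

    # optics / noise
    noise_sd: float = 0.01        # raw-frame noise, fraction of white level
    spectra_noise_sd: float = 0.002  # residual per-ROI spectral noise
    jitter_sd_px: float = 0.5

    # preprocessing
    sg_window: int = 11
    sg_poly_order: int = 2
    trim_lo_nm: float = 420.0
    trim_hi_nm: float = 1600.0
    fusion_boundary_nm: float = 1000.0

    # availability
    availability_spec: str = "dense"

    # selection
    top_n: int = 20
    r_threshold: float = 0.8
    max_keep: int = 6
    stale_limit: int = 5
    k_neighbors: int = 10

    # calibration
    validation_fruit_per_origin: int = 2
    calibration_frac: float = 0.65
    cross_validation_frac: float = 0.15
    n_replicates: int = 20
    hidden_units: int = 4
    learning_rate: float = 0.3
    max_val_fail: int = 15
    mse_goal: float = 1e-4
    max_epochs: int = 500

    # mapping
    mask_method: str = "fixed"
    mask_threshold: float = 0.2
    tukey_alpha: float = 0.05

    extras: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["raster"] = list(d["raster"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "raster" in d:
            d["raster"] = tuple(d["raster"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)


def demo_config(seed: int = 0) -> PipelineConfig:
    """Reduced problem sizes for an end-to-end run in a few minutes."""
    return PipelineConfig(
        seed=seed,
        raster=(128, 128),
        mm_per_px=1.0,
        n_map_fruit=2,
        n_replicates=3,
        max_epochs=120,
    )
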