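"""Run configuration: flat sectioned key-value files, hashed for provenance.

A run is reproducible from the config plus its seed alone; every output table
carries the config hash in a ``#`` header line.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from chlorokin.errors import ConfigError
from chlorokin.protocol import MeasurementProtocol
from chlorokin.synthgen import KineticParams, NoiseConfig, PchlideParams


@dataclass
class RunConfig:
    """Everything a simulate/analyze run needs, serializable to YAML."""

    protocol: MeasurementProtocol = field(default_factory=MeasurementProtocol)
    layout: dict = field(
        default_factory=lambda: {
            "grid_rows": 3,
            "areas_per_row": 5,
            "replicate_cells_per_variant": 3,
            "seeds_per_area": 40,
            "seedlings_per_cell": 30,
            "plate_size_mm": [120.0, 120.0],
        }
    )
    variants: dict[str, dict] = field(
        default_factory=lambda: {
            "wildtype": {},
            "mutant": {"exp_onset": 150.0},
        }
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    image_shape: tuple[int, int] = (1024, 1360)
    segmentation: dict = field(
        default_factory=lambda: {
            "method": "otsu",
            "manual_threshold": None,
            "saturation_fraction_max": 0.001,
            "target_time_min": 180.0,
            "band_fractions": [0.25, 0.45, 0.30],
        }
    )
    stats: dict = field(
        default_factory=lambda: {"alpha": 0.05, "model": "welch", "zone": "cotyledon"}
    )
    rng_seed: int = 0

    def kinetics_per_variant(self) -> dict[str, KineticParams]:
        return {name: KineticParams(**over) for name, over in self.variants.items()}

    def pchlide_per_variant(self) -> dict[str, PchlideParams]:
        return {name: PchlideParams() for name in self.variants}

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol.to_dict(),
            "layout": dict(self.layout),
            "variants": {k: dict(v) for k, v in self.variants.items()},
            "noise": {
                "read_sd": self.noise.read_sd,
                "shot_coeff": self.noise.shot_coeff,
                "cell_cv": self.noise.cell_cv,
                "background_level": self.noise.background_level,
            },
            "image_shape": list(self.image_shape),
            "segmentation": dict(self.segmentation),
            "stats": dict(self.stats),
            "rng_seed": self.rng_seed,
        }

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def metadata(self) -> dict:
        meta = {"config_hash": self.config_hash(), "rng_seed": self.rng_seed}
        for k, v in self.protocol.to_dict().items():
            meta[f"protocol.{k}"] = v
        return meta

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        kwargs = {}
        if "protocol" in raw:
            p = dict(raw["protocol"])
            if "detection_band_nm" in p:
                p["detection_band_nm"] = tuple(p["detection_band_nm"])
            kwargs["protocol"] = MeasurementProtocol(**p)
        if "noise" in raw:
            kwargs["noise"] = NoiseConfig(**raw["noise"])
        for key in ("layout", "variants", "segmentation", "stats", "rng_seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "image_shape" in raw:
            kwargs["image_shape"] = tuple(raw["image_shape"])
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
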