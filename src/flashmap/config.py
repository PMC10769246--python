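"""Run configuration: one YAML file drives the whole pipeline.

A run config has ``geometry``, ``imaging``, ``drift``, ``localization``,
``registration`` and ``proximity`` sections plus a master ``seed`` and a
``mode`` (``list`` or ``frame``).  Unknown keys are rejected; a fully
defaulted config is valid and can be dumped for self-documentation.

Stage seeds are fanned out from the master seed with a counter-based
scheme: stage ``k`` uses ``numpy.random.SeedSequence(master_seed,
spawn_key=(k,))``, so any stage can be re-run in isolation and still see
the same stream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_seed", "STAGE_INDICES", "ConfigError"]


class ConfigError(ValueError):
    pass


#: Stage indices of the seed fan-out scheme (recorded in the manifest).
STAGE_INDICES = {
    "sites": 0,
    "blinking": 1,
    "drift": 2,
    "camera": 3,
    "list_noise": 4,
    "bootstrap": 5,
}


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed sequence derived from the master seed."""
    return np.random.SeedSequence(master_seed, spawn_key=(STAGE_INDICES[stage],))


_GEOMETRY_KEYS = {
    "preset",
    "delta",
    "ribbon_length",
    "site_density_per_um",
    "membrane_jitter_sigma",
    "margin",
    "field_size",
    "axial_offsets",
    "lateral_offsets",
    "backbone",
    "panel",
    "labeling_efficiency",
    "linkage_sigma",
}


@dataclass
class ImagingConfig:
    n_rounds: int = 7
    frames_per_round: int = 30_000
    exposure_ms: float = 25.0
    mean_dark_frames: float = 500.0
    mean_bright_frames: float = 3.0
    photons_per_frame: float = 800.0
    background_photons: float = 5.0
    psf_sigma: float = 130.0
    pixel_size: float = 108.0
    eraser_residual: float = 0.0


@dataclass
class DriftConfig:
    step_sigma: float = 0.05
    velocity_x: float = 0.01
    velocity_y: float = 0.005


@dataclass
class LocalizationConfig:
    threshold_k: float = 5.0
    max_iter: int = 50
    link_max_gap: int = 1
    link_max_dist: float = 100.0


@dataclass
class RegistrationConfig:
    n_segments: int = 10
    bin_size: float = 2.5
    blur_sigma: float = 5.0
    reference_round: int = 0
    min_locs_per_segment: int = 50
    drift_correction: bool = True
    align: bool = True


@dataclass
class ProximityConfig:
    r_max: float = 500.0
    mode: str = "nn"
    min_pairs: int = 10
    n_boot: int = 1000
    ci_level: float = 0.95
    reference_species: str | None = None


@dataclass
class RunConfig:
    """Validated configuration of one simulation + analysis run."""

    geometry: dict = field(
        default_factory=lambda: {
            "preset": "golgi7",
            "labeling_efficiency": 0.7,
            "linkage_sigma": 6.0,
        }
    )
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    seed: int = 0
    mode: str = "list"

    def __post_init__(self) -> None:
        if self.mode not in ("list", "frame"):
            raise ConfigError(f"mode must be 'list' or 'frame', got {self.mode!r}")
        unknown = set(self.geometry) - _GEOMETRY_KEYS
        if unknown:
            raise ConfigError(f"unknown geometry keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        sections = {
            "imaging": ImagingConfig,
            "drift": DriftConfig,
            "localization": LocalizationConfig,
            "registration": RegistrationConfig,
            "proximity": ProximityConfig,
        }
        kwargs: dict = {}
        for name, klass in sections.items():
            sec = raw.pop(name, {}) or {}
            known = {f for f in klass.__dataclass_fields__}
            unknown = set(sec) - known
            if unknown:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            kwargs[name] = klass(**sec)
        kwargs["geometry"] = raw.pop("geometry", None) or RunConfig().geometry
        for key in ("seed", "mode"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ConfigError(f"unknown top-level keys: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def labeling(self) -> tuple[float, float]:
        return (
            float(self.geometry.get("labeling_efficiency", 1.0)),
            float(self.geometry.get("linkage_sigma", 0.0)),
        )
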