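"""Pipeline configuration: one structured mapping validated before any compute."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .aco import ACOParams
from .enhancement import EnhancementParams, LBPParams
from .graphcut import EnergyParams
from .likelihood import ConnectivityParams, IntensityInterval

__all__ = ["RoiConfig", "PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """The pipeline configuration is malformed or inconsistent."""


@dataclass(frozen=True)
class RoiConfig:
    """Computing-space reduction options.

    ``bbox`` is ((z0, z1), (y0, y1), (x0, x1)) inclusive, or None for the
    automatic seed-derived box; ``bbox_mode`` "full" disables cropping.
    ``crossline`` is (row, col) in original coordinates, "auto" for bone-based
    detection, or None to skip quadrant elimination.
    """

    bbox_mode: str = "auto"  # auto | full | manual
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    margin_mm: float = 30.0
    crossline: tuple[int, int] | str | None = None
    quadrant_side: str = "right-bottom"
    bone_threshold: float = 200.0

    def __post_init__(self) -> None:
        if self.bbox_mode not in ("auto", "full", "manual"):
            raise ConfigError(f"bbox_mode must be auto|full|manual, got {self.bbox_mode!r}")
        if self.bbox_mode == "manual" and self.bbox is None:
            raise ConfigError("bbox_mode 'manual' requires an explicit bbox")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs; identical config + seed => identical mask."""

    energy: EnergyParams = EnergyParams()
    connectivity: ConnectivityParams = ConnectivityParams()
    enhancement: EnhancementParams = EnhancementParams()
    aco: ACOParams = ACOParams()
    roi: RoiConfig = RoiConfig()
    interval: IntensityInterval | None = None  # None: estimate from object seeds
    use_intensity_weight: bool = True
    use_aco: bool = True
    seed: int = 0

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict = {}
        nested = {
            "energy": EnergyParams,
            "connectivity": ConnectivityParams,
            "aco": ACOParams,
            "roi": RoiConfig,
        }
        try:
            for key, typ in nested.items():
                if key in data:
                    sub = data.pop(key)
                    kwargs[key] = typ(**sub) if isinstance(sub, dict) else sub
            if "enhancement" in data:
                sub = data.pop("enhancement")
                if isinstance(sub, dict):
                    sub = dict(sub)
                    lbp = sub.pop("lbp", None)
                    if isinstance(lbp, dict):
                        sub["lbp"] = LBPParams(**lbp)
                    elif lbp is not None:
                        sub["lbp"] = lbp
                    sub = EnhancementParams(**sub)
                kwargs["enhancement"] = sub
            if "interval" in data:
                sub = data.pop("interval")
                if isinstance(sub, dict):
                    sub = IntensityInterval(**sub)
                kwargs["interval"] = sub
            known = {f.name for f in fields(cls)}
            unknown = set(data) - known
            if unknown:
                raise ConfigError(f"unknown config keys: {sorted(unknown)}")
            kwargs.update(data)
            cfg = cls(**kwargs)
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(str(exc)) from exc
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(data or {})

    def digest(self) -> str:
        """Stable hash of the full configuration, recorded in provenance logs."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]
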