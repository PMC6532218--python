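"""Run configuration: every analysis parameter in one serializable object."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .stains import IntensityThresholds, StainMatrix
from .zoning import ZoneParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters; echoed verbatim into every run manifest.

    ``config_hash`` is a stable SHA-256 over the canonical JSON form, so two
    runs with identical parameters produce identical manifests.
    """

    um_per_px: float = 0.5
    i0: float = 255.0
    od_floor: float = 0.05
    stain_matrix: list = field(
        default_factory=lambda: StainMatrix.hdab().matrix.tolist())
    thresholds: IntensityThresholds = field(default_factory=IntensityThresholds)
    zone_params: ZoneParams = field(default_factory=ZoneParams)
    nuclei_threshold: float = 0.3
    min_nucleus_area_um2: float = 5.0
    max_nucleus_area_um2: float = 400.0
    quantile_convention: str = "linear"  # numpy type-7, ties to high group
    alpha_significant: float = 0.05
    alpha_stay: float = 0.1  # backward-Wald stay threshold
    survival_horizon_years: float = 5.0
    efs_cols: tuple = ("efs_time", "efs_event")
    os_cols: tuple = ("os_time", "os_event")
    seed: int = 0
    output_dir: str = "ihczone-out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        d["zone_params"] = asdict(self.zone_params)
        d["efs_cols"] = list(self.efs_cols)
        d["os_cols"] = list(self.os_cols)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    @property
    def stains(self) -> StainMatrix:
        return StainMatrix(self.stain_matrix)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = IntensityThresholds(**raw["thresholds"])
        if "zone_params" in raw and isinstance(raw["zone_params"], dict):
            raw["zone_params"] = ZoneParams(**raw["zone_params"])
        for key in ("efs_cols", "os_cols"):
            if key in raw:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
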