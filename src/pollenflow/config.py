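"""Run configuration with YAML round-trip and provenance hashing.

Acquisition constants from the measurement protocol (pixel size per
objective, 5000-particle stop) appear here as configuration defaults, and
every gate threshold is overridable so a run can be replayed exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import yaml

from .gating import GateConfig, MODIFIED_Z_CUTOFF, MULTIPLET_CIRCULARITY_CEILING
from .synthetic import DEFAULT_PARTICLE_LIMIT


@dataclass
class RunConfig:
    """Pipeline configuration; all thresholds within documented ranges."""

    pixel_size_um: float = 0.5          # 0.5 at x40, 1.0 at x20
    ae_threshold: int = 95              # adaptive-erode threshold (50-100)
    loose_dilation_px: int = 4          # vendor-default-like loose mask
    smooth_sigma_px: float = 1.0        # object-mask smoothing
    contrast_floor: float = 0.1         # empty-object floor (intensity units)
    particle_limit: int = DEFAULT_PARTICLE_LIMIT
    outlier_z: float = MODIFIED_Z_CUTOFF
    multiplet_circ_ceiling: float = MULTIPLET_CIRCULARITY_CEILING
    debris_thresholds: Optional[Dict[str, float]] = None
    singlet_threshold: Optional[float] = None
    nonspherical_species: Sequence[str] = field(default_factory=list)
    view_thresholds: Dict[str, float] = field(default_factory=dict)
    seed: int = 0
    rename_map_path: Optional[str] = None
    out_dir: str = "pollenflow_out"

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 50 <= self.ae_threshold <= 100:
            raise ValueError("ae_threshold must be in [50, 100]")
        if self.loose_dilation_px < 1:
            raise ValueError("loose_dilation_px must be >= 1")
        if self.outlier_z <= 0:
            raise ValueError("outlier_z must be positive")
        if self.particle_limit < 1:
            raise ValueError("particle_limit must be >= 1")

    def gate_config(self) -> GateConfig:
        return GateConfig(
            debris_thresholds=self.debris_thresholds,
            singlet_threshold=self.singlet_threshold,
            multiplet_circ_ceiling=self.multiplet_circ_ceiling,
            outlier_z=self.outlier_z,
            nonspherical_species=tuple(self.nonspherical_species),
            view_thresholds=dict(self.view_thresholds),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nonspherical_species"] = list(self.nonspherical_species)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
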