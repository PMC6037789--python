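"""Analysis configuration: the single home of every numeric threshold.

Defaults are the values used throughout the aggregation-analysis literature
for this system class: backbone H-bond N–O distance ≤ 3.5 Å with N–H···O
angle ≥ 120°, inter-peptide heavy-atom contact cutoff 0.55 nm, β-sheet
pairing of ≥ 2 consecutive strand residues linked by ≥ 2 backbone H-bonds,
barrels of at least 4 strands, and a 300 K free-energy landscape.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class AnalysisConfig:
    equilibrium_fraction: float = 0.5   # final fraction of frames used for averages
    contact_cutoff_A: float = 5.5       # inter-peptide heavy-atom contact (Å)
    hbond_dist_A: float = 3.5           # backbone N–O distance cutoff (Å)
    hbond_angle_deg: float = 120.0      # minimum N–H···O angle at H (degrees)
    min_ladder_hbonds: int = 2          # H-bonds required per β-sheet pairing
    min_consecutive_E: int = 2          # strand residues required per pairing
    barrel_min_size: int = 4            # smallest closed sheet called a barrel
    pmf_temperature_K: float = 300.0    # temperature of the PMF transform
    pmf_beta_bin: float = 1.0           # β-content bin width (residues/chain)
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def validate(self) -> "AnalysisConfig":
        positive = {
            "contact_cutoff_A": self.contact_cutoff_A,
            "hbond_dist_A": self.hbond_dist_A,
            "hbond_angle_deg": self.hbond_angle_deg,
            "min_ladder_hbonds": self.min_ladder_hbonds,
            "min_consecutive_E": self.min_consecutive_E,
            "barrel_min_size": self.barrel_min_size,
            "pmf_temperature_K": self.pmf_temperature_K,
            "pmf_beta_bin": self.pmf_beta_bin,
        }
        for key, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{key} must be positive, got {value}")
        if not (0.0 < self.equilibrium_fraction <= 1.0):
            raise ConfigError(
                f"equilibrium_fraction must be in (0, 1], got {self.equilibrium_fraction}"
            )
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path.name}: expected a mapping of options")
        return cls.from_dict(data)
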