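"""Flat pipeline configuration with YAML round trip and a stable hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Every analysis toggle and threshold in one flat record.

    Cut-offs follow the screening instruments (ISI 15, BSI 63); the chi2
    significance threshold is the stringent 1e-8 used for the cortex/rim
    differential tally; stepwise thresholds are conventional partial-F
    defaults.
    """

    region_table: str = ""
    cohort_dir: str = ""
    out_dir: str = "."
    apply_correction: bool = True
    correction_before_atlas: bool = True
    per_cohort_correction: bool = True
    binomial_convention: str = "strict"  # or "at_least"
    priors: str = "equal"  # or "proportional"
    isi_cutoff: int = 15
    bsi_cutoff: int = 63
    chi2_alpha: float = 1e-8
    f_to_enter: float = 3.84
    f_to_remove: float = 2.71
    stepwise_tolerance: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.isi_cutoff <= 0 or self.bsi_cutoff <= 0:
            raise ConfigError("survey cut-offs must be positive integers")
        if not 0.0 < self.chi2_alpha < 1.0:
            raise ConfigError("chi2_alpha must be in (0, 1)")
        if self.binomial_convention not in ("strict", "at_least"):
            raise ConfigError(
                f"unknown binomial_convention {self.binomial_convention!r}")
        if self.priors not in ("equal", "proportional"):
            raise ConfigError(f"unknown priors {self.priors!r}")
        if not self.f_to_enter > self.f_to_remove > 0:
            raise ConfigError("need f_to_enter > f_to_remove > 0")

    @property
    def cutoffs(self) -> dict[str, int]:
        return {"insomnia": self.isi_cutoff, "somatization": self.bsi_cutoff,
                "depression": self.bsi_cutoff, "anxiety": self.bsi_cutoff}

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
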