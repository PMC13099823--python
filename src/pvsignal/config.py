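"""Pipeline configuration: one YAML file drives every stage.

Exactly one input source must be configured: either ``input_dir`` (a
directory of quarterly FAERS-format archives plus a deleted-case list) or
``synthetic`` (a planted-signal generator spec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .signals import PriorParams, SignalConfig
from .synthetic import PlantedAssociation, PlantedSignalSpec


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    target_drug: str = "pralatrexate"
    input_dir: Optional[str] = None
    deleted_list: Optional[str] = None  # defaults to <input_dir>/deleted_caseids.txt
    synthetic: Optional[PlantedSignalSpec] = None
    pt_to_soc: Optional[str] = None  # TSV paths; bundled mock dictionary if None
    drug_synonyms: Optional[str] = None
    signal: SignalConfig = field(default_factory=SignalConfig)
    top_k: int = 50
    output_dir: str = "pvsignal_out"

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of input_dir / synthetic must be configured"
            )
        if self.signal.min_count <= 0:
            raise ConfigError("min_count must be positive")
        for name in ("prr_threshold", "chi2_threshold", "eb05_threshold"):
            if getattr(self.signal, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.synthetic is not None:
            self.synthetic.validate()

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        signal_raw = raw.pop("signal", {}) or {}
        prior_raw = signal_raw.pop("mgps_prior", None)
        signal = SignalConfig(**signal_raw)
        if prior_raw:
            signal.mgps_prior = PriorParams(**prior_raw)
        synthetic_raw = raw.pop("synthetic", None)
        synthetic = None
        if synthetic_raw is not None:
            synthetic_raw = dict(synthetic_raw)
            assoc_raw = synthetic_raw.pop("associations", None)
            bg_raw = synthetic_raw.pop("background_pts", None)
            synthetic = PlantedSignalSpec(**synthetic_raw)
            if assoc_raw is not None:
                synthetic.associations = [PlantedAssociation(**a) for a in assoc_raw]
            if bg_raw is not None:
                synthetic.background_pts = [tuple(x) for x in bg_raw]
        config = cls(signal=signal, synthetic=synthetic, **raw)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        try:
            return cls.from_dict(raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
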