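"""Pipeline configuration: every analysis threshold in one YAML-serialisable object."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Bad or inconsistent pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters for extraction and modelling.

    ``endpoint_features`` pairs each endpoint with its reference-model
    covariates and the single radiomics feature whose added value is
    tested: Short Run Emphasis of the contra-lateral parotid for
    12-month xerostomia, maxHU of the submandibular glands for sticky
    saliva.  The pairing is configurable for methodological exploration.
    """

    hu_artifact_threshold: float = 2000.0
    subgroup_min_n: int = 20
    exclusion_fraction_cut: float = 0.5
    alpha: float = 0.05
    normalise_within_subgroup: bool = True
    baseline_encoding: str = "numeric"  # or "binary" (grade >= 3)
    smg_pooling: str = "mean"  # combine bilateral SMG feature values
    endpoint_features: dict = field(
        default_factory=lambda: {
            "xer12m": {
                "baseline": "baseline_xer_grade",
                "dose": "mean_dose_contra_parotid",
                "feature": "parotid_sre_2d",
            },
            "ss12m": {
                "baseline": "baseline_ss_grade",
                "dose": "mean_dose_bilateral_smg",
                "feature": "smg_maxhu",
            },
        }
    )

    def __post_init__(self) -> None:
        if self.hu_artifact_threshold <= 200:
            raise ConfigError("hu_artifact_threshold must exceed 200 HU")
        if self.subgroup_min_n < 2:
            raise ConfigError("subgroup_min_n must be >= 2")
        if not 0 < self.exclusion_fraction_cut <= 1:
            raise ConfigError("exclusion_fraction_cut must lie in (0, 1]")
        if self.baseline_encoding not in ("numeric", "binary"):
            raise ConfigError(f"unknown baseline_encoding {self.baseline_encoding!r}")
        if self.smg_pooling not in ("mean",):
            raise ConfigError(f"unknown smg_pooling {self.smg_pooling!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run metadata."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
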