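"""Run configuration: one object tying every stage's settings together,
round-trippable through YAML."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .features import ExtractionConfig
from .synthetic import SyntheticConfig


@dataclass
class RunConfig:
    """Settings for an end-to-end run.

    ``mode`` selects whether the simulate stage emits a feature table
    directly (``"features"``) or per-lesion volumes to be fed through the
    extractor (``"volumes"``).
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    embedding_method: str = "ZSCORE"
    n_components: int | None = None
    inclusive_thresholds: bool = True
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    mode: str = "features"
    seed: int = 0
    output_dir: str = "petsil_out"
    verbosity: int = 1

    def validate(self) -> None:
        self.synthetic.validate()
        self.extraction.validate()
        if self.mode not in ("features", "volumes"):
            raise ConfigurationError("mode must be 'features' or 'volumes'")
        if not self.k_range:
            raise ConfigurationError("k_range must be non-empty")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        ext = d["extraction"]
        ext["absolute_bounds"] = list(ext["absolute_bounds"])
        if ext["feature_roster"] is not None:
            ext["feature_roster"] = list(ext["feature_roster"])
        syn = d["synthetic"]
        syn["lesion_count_law"] = {int(k): float(v)
                                   for k, v in syn["lesion_count_law"].items()}
        syn["suv_law"] = {k: list(map(float, v))
                          for k, v in syn["suv_law"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        if "suv_law" in syn:
            syn["suv_law"] = {k: tuple(v) for k, v in syn["suv_law"].items()}
        if "lesion_count_law" in syn:
            syn["lesion_count_law"] = {int(k): float(v)
                                       for k, v in syn["lesion_count_law"].items()}
        ext = dict(d.pop("extraction", {}))
        if "absolute_bounds" in ext:
            ext["absolute_bounds"] = tuple(ext["absolute_bounds"])
        if ext.get("feature_roster") is not None:
            ext["feature_roster"] = tuple(ext["feature_roster"])
        return cls(synthetic=SyntheticConfig(**syn),
                   extraction=ExtractionConfig(**ext), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the settings, logged with every output."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
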