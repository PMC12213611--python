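"""Analysis configuration.

Collects the thresholds and conventions that the pipeline treats as fixed
choices: which root status classes enter FRC, the shallow/deep boundary, the
minimum number of cumulative points for a beta fit, how standardization
groups are formed, and how tundra sites are classed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    #: root status classes entering FRC: "all" (live + dead) or "live"
    root_status: str = "all"
    #: shallow/deep boundary, cm; [0, boundary) shallow, [boundary, 200] deep
    shallow_boundary: float = 30.0
    #: minimum cumulative points for a beta fit
    min_points: int = 3
    #: standardization grouping for 1:1 residuals: "pooled" or "by-ecosystem"
    standardization: str = "pooled"
    #: analysis class assigned to tundra-tagged sites
    tundra_as: str = "grassland"
    #: lower/upper bounds of the beta search interval
    beta_bounds: tuple[float, float] = (0.5, 0.99999)

    def __post_init__(self) -> None:
        if self.root_status not in ("all", "live"):
            raise ValueError(f"root_status must be 'all' or 'live', got {self.root_status!r}")
        if self.standardization not in ("pooled", "by-ecosystem"):
            raise ValueError("standardization must be 'pooled' or 'by-ecosystem'")
        if not 0 < self.shallow_boundary < 200:
            raise ValueError("shallow_boundary must be in (0, 200) cm")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")

    def ecosystem_class(self, ecosystem: str) -> str:
        """Analysis class for an ecosystem tag (tundra folds into grassland
        by default; the tag itself is preserved on the records)."""
        if ecosystem == "tundra":
            return self.tundra_as
        return ecosystem

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "beta_bounds" in raw:
            raw["beta_bounds"] = tuple(raw["beta_bounds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["beta_bounds"] = list(d["beta_bounds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


DEFAULT_CONFIG = AnalysisConfig()
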