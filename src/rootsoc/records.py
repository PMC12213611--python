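"""Domain record types for site profiles.

All depths are in cm, positive downward, with 0 at the top of the uppermost
horizon (organic horizons share the same downward axis). Depth intervals are
half-open [top, bottom). Stocks are kg C m^-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


ECOSYSTEMS = ("forest", "grassland", "shrubland", "cultivated", "tundra")
ROOT_STATUSES = ("live", "dead")
DIAMETER_PROTOCOLS = ("2mm", "4mm")

#: MAT offset in the aridity index MAP/(MAT + 13); MAT <= -13 makes the index
#: undefined.
ARIDITY_MAT_OFFSET = 13.0


class ValidationError(ValueError):
    """A row or a collection of rows violates a type invariant."""


class SchemaError(ValidationError):
    """An input table is missing required columns."""

    def __init__(self, table: str, missing: list[str]):
        self.table = table
        self.missing = list(missing)
        super().__init__(f"table {table!r} is missing columns: {', '.join(missing)}")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class SiteMeta:
    """Site-level metadata: climate, ecosystem type, profile depth."""

    site_id: str
    ecosystem: str
    mat: float                      # mean annual temperature, degC
    map_mm: float                   # mean annual precipitation, mm yr^-1
    max_profile_depth: float        # cm; pit depth (2 m or bedrock-truncated)
    litterfall: float | None = None  # g m^-2 yr^-1, optional (forests)

    def validate(self) -> "SiteMeta":
        _require(bool(self.site_id), "site_id must be non-empty")
        _require(self.ecosystem in ECOSYSTEMS,
                 f"site {self.site_id}: unknown ecosystem {self.ecosystem!r}")
        _require(self.map_mm >= 0, f"site {self.site_id}: MAP must be >= 0")
        _require(0 < self.max_profile_depth <= 200,
                 f"site {self.site_id}: max_profile_depth must be in (0, 200] cm")
        return self

    @property
    def aridity_defined(self) -> bool:
        return self.mat > -ARIDITY_MAT_OFFSET


@dataclass(frozen=True)
class SoilHorizon:
    """One taxonomic soil horizon with its lab chemistry."""

    site_id: str
    horizon_label: str
    top: float           # cm
    bottom: float        # cm
    is_organic: bool
    oc_pct: float        # organic C, % of dry mass
    bulk_density: float  # g cm^-3
    clay_pct: float      # %

    def validate(self) -> "SoilHorizon":
        _require(0 <= self.top < self.bottom,
                 f"horizon {self.site_id}/{self.horizon_label}: need 0 <= top < bottom, "
                 f"got [{self.top}, {self.bottom})")
        _require(0 <= self.oc_pct <= 60,
                 f"horizon {self.site_id}/{self.horizon_label}: oc_pct out of [0, 60]")
        _require(self.bulk_density > 0,
                 f"horizon {self.site_id}/{self.horizon_label}: bulk_density must be > 0")
        _require(0 <= self.clay_pct <= 100,
                 f"horizon {self.site_id}/{self.horizon_label}: clay_pct out of [0, 100]")
        return self

    @property
    def thickness(self) -> float:
        return self.bottom - self.top


@dataclass(frozen=True)
class RootIncrement:
    """One fixed-depth root sample (10- or 20-cm monolith increment)."""

    site_id: str
    top: float
    bottom: float
    biomass: float           # g m^-2 within the increment
    root_c_pct: float        # %
    status: str              # live | dead
    diameter_protocol: str   # 2mm | 4mm

    def validate(self) -> "RootIncrement":
        _require(0 <= self.top < self.bottom,
                 f"root increment {self.site_id} [{self.top}, {self.bottom}): "
                 "need 0 <= top < bottom")
        _require(self.biomass >= 0,
                 f"root increment {self.site_id} [{self.top}, {self.bottom}): "
                 "biomass must be >= 0")
        _require(0 < self.root_c_pct <= 100,
                 f"root increment {self.site_id} [{self.top}, {self.bottom}): "
                 "root_c_pct out of (0, 100]")
        _require(self.status in ROOT_STATUSES,
                 f"root increment {self.site_id}: unknown status {self.status!r}")
        _require(self.diameter_protocol in DIAMETER_PROTOCOLS,
                 f"root increment {self.site_id}: unknown diameter protocol "
                 f"{self.diameter_protocol!r}")
        return self


@dataclass(frozen=True)
class LayerStock:
    """Aligned per-layer FRC and SOC stocks on the horizon grid."""

    site_id: str
    top: float
    bottom: float
    is_organic: bool
    frc: float       # kg C m^-2
    soc: float       # kg C m^-2
    clay_pct: float

    def validate(self) -> "LayerStock":
        _require(0 <= self.top < self.bottom,
                 f"layer {self.site_id} [{self.top}, {self.bottom}): bad bounds")
        _require(self.frc >= 0 and self.soc >= 0,
                 f"layer {self.site_id} [{self.top}, {self.bottom}): negative stock")
        return self

    @property
    def thickness(self) -> float:
        return self.bottom - self.top


@dataclass(frozen=True)
class SiteAggregate:
    """Per-site stock sums by profile, horizon class and 30-cm depth split."""

    site_id: str
    ecosystem: str
    frc_total: float
    soc_total: float
    frc_organic: float
    soc_organic: float
    frc_mineral: float
    soc_mineral: float
    frc_shallow: float
    soc_shallow: float
    frc_deep: float
    soc_deep: float
    aridity: float            # mm degC^-1; NaN when MAT <= -13
    clay_whole: float         # depth-weighted mean clay, %
    clay_shallow: float
    clay_deep: float
    mat: float
    map_mm: float
    max_profile_depth: float
    litterfall: float | None = None
    has_organic: bool = False

    def validate(self, tol: float = 1e-9) -> "SiteAggregate":
        _require(math.isclose(self.frc_total, self.frc_organic + self.frc_mineral,
                              rel_tol=0, abs_tol=tol * max(1.0, abs(self.frc_total))),
                 f"{self.site_id}: organic+mineral FRC does not sum to total")
        _require(math.isclose(self.soc_total, self.soc_organic + self.soc_mineral,
                              rel_tol=0, abs_tol=tol * max(1.0, abs(self.soc_total))),
                 f"{self.site_id}: organic+mineral SOC does not sum to total")
        _require(math.isclose(self.frc_total, self.frc_shallow + self.frc_deep,
                              rel_tol=0, abs_tol=tol * max(1.0, abs(self.frc_total))),
                 f"{self.site_id}: shallow+deep FRC does not sum to total")
        _require(math.isclose(self.soc_total, self.soc_shallow + self.soc_deep,
                              rel_tol=0, abs_tol=tol * max(1.0, abs(self.soc_total))),
                 f"{self.site_id}: shallow+deep SOC does not sum to total")
        return self


# Exclusion reason codes. Every dropped site carries one; nothing is dropped
# silently.
EXCL_NO_ROOT_DATA = "no_root_data"
EXCL_NO_HORIZON_DATA = "no_horizon_data"
EXCL_ZERO_STOCK = "zero_total_stock"
EXCL_TOO_FEW_POINTS = "too_few_measurements"


@dataclass
class SiteProfile:
    """A site's metadata plus its ordered horizons and root increments.

    ``excluded``/``exclusion_reason`` implement the explicit-exclusion
    contract (e.g. sites present in metadata but lacking root rows).
    """

    meta: SiteMeta
    horizons: list[SoilHorizon] = field(default_factory=list)
    increments: list[RootIncrement] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def site_id(self) -> str:
        return self.meta.site_id

    def exclude(self, reason: str) -> None:
        self.excluded = True
        self.exclusion_reason = reason


def check_disjoint_sorted(intervals: list[tuple[float, float]], what: str,
                          site_id: str) -> None:
    """Raise ValidationError listing offending rows if intervals overlap or
    are out of order."""
    bad = []
    for i in range(1, len(intervals)):
        if intervals[i][0] < intervals[i - 1][1]:
            bad.append(i)
    if bad:
        rows = "; ".join(
            f"row {i}: [{intervals[i - 1][0]}, {intervals[i - 1][1]}) then "
            f"[{intervals[i][0]}, {intervals[i][1]})" for i in bad)
        raise ValidationError(
            f"{what} for site {site_id} overlap or are unsorted: {rows}")
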