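"""Synthetic continental-gradient site generator with known ground truth.

Emulates the structure of one-time 2-m "megapit" excavations on a
continental observatory network: root biomass sampled on a fixed grid of
10-cm increments to 1 m then 20-cm increments to 2 m, soil chemistry
sampled once per taxonomic horizon whose boundaries are independent of the
increment grid, and per-site climate metadata spanning MAT -12..25 degC
and MAP 100..2500 mm. Ecosystem defaults mirror the study conditions:
15 grassland-class sites (three of them high-latitude tundra outliers with
~2.5x root biomass), 25 forests, 3 shrublands, 1 cultivated site;
grassland mean MAP about half the forest mean; organic horizons mostly in
forests and tundra.

Ground truth per site: the depth-distribution parameters (beta_frc,
beta_soc), the whole-profile totals, and the ecosystem coupling
SOC_total = a + b * FRC_total + N(0, sigma^2) (grassland default
a = 8.5, b = 15.5; forests uncoupled, b = 0).

Noise acts at two scales that can be tuned independently: multiplicative
log-normal noise on the within-profile layer *fractions* (renormalized, so
site totals are untouched) and the additive site-level sigma on the
coupling. Everything is driven by one integer-seeded generator
(numpy PCG64), so a seed fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .accrual import classify_residual
from .records import ValidationError

ECOSYSTEM_ORDER = ("grassland", "forest", "shrubland", "cultivated")

SITES_HEADER = ["site_id", "ecosystem", "mat", "map", "max_profile_depth", "litterfall"]
HORIZONS_HEADER = ["site_id", "horizon_label", "top", "bottom", "is_organic",
                   "oc_pct", "bulk_density", "clay_pct"]
ROOTS_HEADER = ["site_id", "top", "bottom", "biomass", "root_c_pct", "status",
                "diameter_protocol"]


@dataclass(frozen=True)
class EcosystemParams:
    """Per-ecosystem generating distributions."""

    mat_range: tuple[float, float]
    map_range: tuple[float, float]          # mm
    beta_frc: tuple[float, float]           # (mean, sd), clipped to (0.85, 0.995)
    beta_soc: tuple[float, float]
    frc_total: tuple[float, float]          # lognormal (mean, sd), kg C m^-2
    coupling_a: float                       # SOC intercept, kg m^-2
    coupling_b: float                       # kg SOC per kg FRC
    coupling_sigma: float                   # additive site-level sd, kg m^-2
    organic_prob: float
    clay: tuple[float, float]               # site mean clay (mean, sd), %
    litterfall: tuple[float, float] | None = None  # g m^-2 yr^-1, forests


DEFAULT_ECOSYSTEMS: dict[str, EcosystemParams] = {
    # grassland coupling a=8.5, b=15.5 with sigma tuned so r^2 ~ 0.8 at the
    # default FRC spread; MAP mean about half the forest mean
    "grassland": EcosystemParams(
        mat_range=(0.0, 25.0), map_range=(100.0, 1450.0),
        beta_frc=(0.94, 0.015), beta_soc=(0.95, 0.015),
        frc_total=(0.4, 0.25),
        coupling_a=8.5, coupling_b=15.5, coupling_sigma=2.0,
        organic_prob=0.05, clay=(22.0, 8.0)),
    "forest": EcosystemParams(
        mat_range=(-5.0, 25.0), map_range=(600.0, 2500.0),
        beta_frc=(0.96, 0.02), beta_soc=(0.97, 0.015),
        frc_total=(0.5, 0.3),
        coupling_a=11.0, coupling_b=0.0, coupling_sigma=6.0,
        organic_prob=0.6, clay=(18.0, 8.0),
        litterfall=(450.0, 120.0)),
    "shrubland": EcosystemParams(
        mat_range=(5.0, 25.0), map_range=(100.0, 600.0),
        beta_frc=(0.95, 0.015), beta_soc=(0.95, 0.015),
        frc_total=(0.25, 0.1),
        coupling_a=6.0, coupling_b=0.0, coupling_sigma=2.0,
        organic_prob=0.05, clay=(15.0, 6.0)),
    "cultivated": EcosystemParams(
        mat_range=(5.0, 15.0), map_range=(400.0, 1000.0),
        beta_frc=(0.93, 0.01), beta_soc=(0.94, 0.01),
        frc_total=(0.3, 0.1),
        coupling_a=8.0, coupling_b=0.0, coupling_sigma=2.0,
        organic_prob=0.0, clay=(25.0, 6.0)),
    # high-latitude tundra outlier sites: analyzed under the grassland
    # class; root biomass inflated ~2.5x after the coupling is drawn
    "tundra": EcosystemParams(
        mat_range=(-12.0, -2.0), map_range=(100.0, 800.0),
        beta_frc=(0.92, 0.015), beta_soc=(0.93, 0.015),
        frc_total=(0.4, 0.25),
        coupling_a=8.5, coupling_b=15.5, coupling_sigma=2.0,
        organic_prob=0.9, clay=(12.0, 5.0)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    #: grassland count includes the tundra-tagged outliers
    n_sites: dict = field(default_factory=lambda: {
        "grassland": 15, "forest": 25, "shrubland": 3, "cultivated": 1})
    ecosystems: dict = field(default_factory=lambda: dict(DEFAULT_ECOSYSTEMS))
    #: high-FRC tundra outliers among the grassland-class sites
    outlier_tundra: int = 3
    outlier_frc_multiplier: float = 2.5
    #: CV of the multiplicative log-normal layer-fraction noise
    noise_cv: float = 0.10
    #: bedrock truncation: profile depth (cm) -> weight
    depth_weights: dict = field(default_factory=lambda: {200.0: 0.7, 140.0: 0.15,
                                                         100.0: 0.15})
    #: standardized depth-class coupling (z_soc = slope * z_frc + N(0, sd))
    deep_slope: float = 1.2
    shallow_slope: float = 0.9
    depth_slope_noise_sd: float = 0.5
    #: fraction of sites on the 4-mm root diameter protocol (13 of 43)
    p_4mm: float = 13.0 / 43.0
    #: share of standing root biomass classified dead
    dead_fraction: float = 0.2
    max_retries: int = 100


@dataclass
class SyntheticDataset:
    """The three flat input tables plus the hidden ground truth.

    `truth` is emitted alongside the data for test assertions only; pipeline
    stages under test never read it.
    """

    sites: pd.DataFrame
    horizons: pd.DataFrame
    roots: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("sites", self.sites), ("horizons", self.horizons),
                         ("roots", self.roots), ("truth", self.truth)):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a log-normal with the given arithmetic mean and sd."""
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return float(rng.lognormal(math.log(mean) - s2 / 2.0, math.sqrt(s2)))


def _fraction_noise(rng: np.random.Generator, fractions: np.ndarray,
                    cv: float) -> np.ndarray:
    """Multiplicative log-normal noise on layer fractions, renormalized so
    the profile total is conserved exactly."""
    if cv <= 0:
        return fractions
    s2 = math.log(1.0 + cv ** 2)
    noisy = fractions * rng.lognormal(-s2 / 2.0, math.sqrt(s2), size=len(fractions))
    return noisy / noisy.sum()


def increment_grid(depth: float) -> list[tuple[float, float]]:
    """The fixed root sampling grid: 10-cm increments to 1 m, 20-cm below,
    truncated at the profile depth."""
    bounds = []
    top = 0.0
    while top < min(depth, 100.0):
        bot = min(top + 10.0, depth)
        bounds.append((top, bot))
        top = bot
    while top < depth:
        bot = min(top + 20.0, depth)
        bounds.append((top, bot))
        top = bot
    return bounds


def _beta_fractions(beta: float, bounds: list[tuple[float, float]]) -> np.ndarray:
    """Within-profile stock fractions implied by Y(d) = 1 - beta^d over the
    given layer bounds, normalized to the profile depth."""
    depth = bounds[-1][1]
    total = 1.0 - beta ** depth
    return np.array([((1.0 - beta ** b) - (1.0 - beta ** t)) / total
                     for t, b in bounds])


def _draw_horizon_bounds(rng: np.random.Generator, depth: float,
                         organic: bool) -> tuple[list[tuple[float, float]], int]:
    """Horizon boundaries independent of the increment grid: an optional
    thin organic cap, then 2-6 mineral horizons with >= 5 cm thickness.
    Returns (bounds, number of organic horizons)."""
    bounds = []
    lo = 0.0
    n_org = 0
    if organic:
        o_bot = float(rng.uniform(3.0, 10.0))
        bounds.append((0.0, o_bot))
        lo = o_bot
        n_org = 1
    n_m = int(rng.integers(2, 7))
    cuts = None
    for _ in range(50):
        cand = np.sort(rng.uniform(lo + 5.0, depth - 5.0, size=n_m - 1))
        edges = np.concatenate([[lo], cand, [depth]])
        if np.all(np.diff(edges) >= 5.0):
            cuts = edges
            break
    if cuts is None:
        cuts = np.linspace(lo, depth, n_m + 1)
    bounds.extend((float(cuts[i]), float(cuts[i + 1])) for i in range(len(cuts) - 1))
    return bounds, n_org


def draw_site_totals(ecosystem: str, n: int, rng: np.random.Generator,
                     config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Site-level truth draws for one ecosystem: FRC totals and the coupled
    SOC totals (SOC = a + b*FRC + N(0, sigma)), without profile structure.

    This is the stage that defines the coupling; the profile builder
    distributes exactly these totals over layers.
    """
    config = config or GeneratorConfig()
    p = config.ecosystems[ecosystem]
    rows = []
    for i in range(n):
        frc = _lognormal(rng, *p.frc_total)
        for _ in range(config.max_retries):
            soc = p.coupling_a + p.coupling_b * frc + rng.normal(0.0, p.coupling_sigma)
            if soc > 0.3:
                break
        else:
            raise ValidationError(
                f"could not draw positive SOC total for {ecosystem} "
                f"(a={p.coupling_a}, b={p.coupling_b}, sigma={p.coupling_sigma})")
        rows.append({"ecosystem": ecosystem, "frc_total": frc, "soc_total": soc})
    return pd.DataFrame(rows)


def generate(config: GeneratorConfig | None = None,
             outdir=None) -> SyntheticDataset:
    """Generate a full synthetic site collection.

    Returns the three input tables (sites/horizons/roots) plus the ground
    truth; optionally writes them as CSVs. The same seed yields
    byte-identical CSV output.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    depths = np.array(sorted(config.depth_weights))
    dweights = np.array([config.depth_weights[d] for d in depths], dtype=float)
    dweights = dweights / dweights.sum()

    site_rows, horizon_rows, root_rows, truth_rows = [], [], [], []
    idx = 0
    for eco in ECOSYSTEM_ORDER:
        n = config.n_sites.get(eco, 0)
        for j in range(n):
            # first outlier_tundra grassland-class sites carry the tundra tag
            tag = "tundra" if (eco == "grassland" and j < config.outlier_tundra) else eco
            p = config.ecosystems[tag]
            idx += 1
            site_id = f"S{idx:03d}"
            mat = float(rng.uniform(*p.mat_range))
            map_mm = float(rng.uniform(*p.map_range))
            depth = float(rng.choice(depths, p=dweights))
            beta_frc = float(np.clip(rng.normal(*p.beta_frc), 0.85, 0.995))
            beta_soc = float(np.clip(rng.normal(*p.beta_soc), 0.85, 0.995))
            clay_site = float(np.clip(rng.normal(*p.clay), 1.0, 60.0))
            litterfall = (float(max(rng.normal(*p.litterfall), 0.0))
                          if p.litterfall else None)
            protocol = "4mm" if rng.random() < config.p_4mm else "2mm"
            root_c_pct = float(np.clip(rng.normal(46.0, 3.0), 35.0, 55.0))

            totals = draw_site_totals(tag, 1, rng, config).iloc[0]
            frc_total = float(totals["frc_total"])
            soc_total = float(totals["soc_total"])
            multiplier = 1.0
            if tag == "tundra":
                multiplier = config.outlier_frc_multiplier
                frc_total *= multiplier  # inflate roots after coupling: breaks it

            # --- horizons + SOC
            organic = rng.random() < p.organic_prob
            hbounds, n_org = _draw_horizon_bounds(rng, depth, organic)
            frac = _fraction_noise(rng, _beta_fractions(beta_soc, hbounds),
                                   config.noise_cv)
            for k, ((top, bot), f) in enumerate(zip(hbounds, frac)):
                is_org = k < n_org
                soc_k = soc_total * float(f)
                th = bot - top
                bd = float(rng.uniform(0.10, 0.35) if is_org
                           else rng.uniform(0.9, 1.6))
                oc = soc_k / (bd * th * 10.0) * 100.0
                if oc > 60.0:
                    bd = soc_k * 100.0 / (55.0 * th * 10.0)
                    oc = 55.0
                horizon_rows.append({
                    "site_id": site_id,
                    "horizon_label": ("O" if is_org else "M") + str(k + 1),
                    "top": top, "bottom": bot, "is_organic": is_org,
                    "oc_pct": oc, "bulk_density": bd,
                    "clay_pct": float(np.clip(clay_site + rng.normal(0.0, 2.0),
                                              0.0, 100.0)),
                })

            # --- root increments + FRC
            ibounds = increment_grid(depth)
            ifrac = _fraction_noise(rng, _beta_fractions(beta_frc, ibounds),
                                    config.noise_cv)
            for (top, bot), f in zip(ibounds, ifrac):
                frc_k = frc_total * float(f)
                biomass = frc_k * 1000.0 / (root_c_pct / 100.0)
                for status, share in (("live", 1.0 - config.dead_fraction),
                                      ("dead", config.dead_fraction)):
                    if share <= 0:
                        continue
                    root_rows.append({
                        "site_id": site_id, "top": top, "bottom": bot,
                        "biomass": biomass * share, "root_c_pct": root_c_pct,
                        "status": status, "diameter_protocol": protocol,
                    })

            site_rows.append({
                "site_id": site_id, "ecosystem": tag, "mat": mat, "map": map_mm,
                "max_profile_depth": depth, "litterfall": litterfall,
            })
            truth_rows.append({
                "site_id": site_id, "ecosystem": tag,
                "beta_frc": beta_frc, "beta_soc": beta_soc,
                "frc_total": frc_total, "soc_total": soc_total,
                "frc_multiplier": multiplier,
                "coupling_a": p.coupling_a, "coupling_b": p.coupling_b,
                "coupling_sigma": p.coupling_sigma,
                "max_profile_depth": depth,
            })

    ds = SyntheticDataset(
        sites=pd.DataFrame(site_rows, columns=SITES_HEADER),
        horizons=pd.DataFrame(horizon_rows, columns=HORIZONS_HEADER),
        roots=pd.DataFrame(root_rows, columns=ROOTS_HEADER),
        truth=pd.DataFrame(truth_rows),
    )
    if outdir is not None:
        ds.write(outdir)
    return ds


def generate_standardized_depth_cohort(n: int, rng: np.random.Generator,
                                       deep_slope: float = 1.2,
                                       shallow_slope: float = 0.9,
                                       noise_sd: float = 0.5,
                                       ecosystem: str = "grassland",
                                       ) -> pd.DataFrame:
    """Depth-class FRC-SOC pairs on the standardized (z) scale.

    z_frc ~ N(0, 1) and z_soc = slope * z_frc + N(0, noise_sd) per depth
    class. The z scale is anchored to a notional wider pooled population,
    which is how within-cohort slopes above 1 arise; the cohort is
    deliberately not re-standardized.
    """
    frames = []
    for depth_class, slope in (("shallow", shallow_slope), ("deep", deep_slope)):
        zf = rng.standard_normal(n)
        zs = slope * zf + rng.normal(0.0, noise_sd, size=n)
        resid = zs - zf
        frames.append(pd.DataFrame({
            "site_id": [f"S{i + 1:03d}" for i in range(n)],
            "ecosystem": ecosystem,
            "depth_class": depth_class,
            "z_frc": zf, "z_soc": zs, "residual": resid,
            "label": [classify_residual(r) for r in resid],
        }))
    return pd.concat(frames, ignore_index=True)


def generator_config_from_yaml(path, seed: int | None = None) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML mapping of field overrides.

    Nested ``ecosystems`` entries override individual EcosystemParams
    fields; list values become tuples. A ``seed`` argument overrides any
    seed in the file.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    eco_overrides = raw.pop("ecosystems", {})
    ecosystems = dict(DEFAULT_ECOSYSTEMS)
    for name, overrides in eco_overrides.items():
        base = ecosystems.get(name)
        if base is None:
            raise ValidationError(f"unknown ecosystem {name!r} in generator config")
        fixed = {k: tuple(v) if isinstance(v, (list, tuple)) else v
                 for k, v in overrides.items()}
        ecosystems[name] = replace(base, **fixed)
    if "depth_weights" in raw:
        raw["depth_weights"] = {float(k): float(v)
                                for k, v in raw["depth_weights"].items()}
    if seed is not None:
        raw["seed"] = seed
    return GeneratorConfig(ecosystems=ecosystems, **raw)


# ------------------------------------------------------------- fixtures

def _fixture_tables(site_specs) -> SyntheticDataset:
    """Build a tiny dataset from (site_id, frc_total, soc_factor) specs with
    one mineral horizon [0, 100) and two root increments, zero noise."""
    sites, horizons, roots, truth = [], [], [], []
    for site_id, frc, soc in site_specs:
        sites.append({"site_id": site_id, "ecosystem": "grassland", "mat": 10.0,
                      "map": 800.0, "max_profile_depth": 100.0, "litterfall": None})
        # soc_stock(oc, 1.0, 100) = 10*oc, so oc = soc/10 reproduces soc exactly
        horizons.append({"site_id": site_id, "horizon_label": "M1", "top": 0.0,
                         "bottom": 100.0, "is_organic": False,
                         "oc_pct": soc / 10.0, "bulk_density": 1.0,
                         "clay_pct": 20.0})
        for top, bot, share in ((0.0, 50.0, 0.7), (50.0, 100.0, 0.3)):
            roots.append({"site_id": site_id, "top": top, "bottom": bot,
                          "biomass": frc * share * 1000.0 / 0.5,
                          "root_c_pct": 50.0, "status": "live",
                          "diameter_protocol": "2mm"})
        truth.append({"site_id": site_id, "frc_total": frc, "soc_total": soc})
    return SyntheticDataset(
        sites=pd.DataFrame(sites, columns=SITES_HEADER),
        horizons=pd.DataFrame(horizons, columns=HORIZONS_HEADER),
        roots=pd.DataFrame(roots, columns=ROOTS_HEADER),
        truth=pd.DataFrame(truth))


def make_fixture(name: str) -> SyntheticDataset:
    """Tiny deterministic datasets for unit tests.

    Registry: "perfect-1to1" (SOC exactly affine in FRC, so every 1:1
    residual is 0), "all-accrual" (grassland sites all above the pooled 1:1
    line, forests all below), "two-horizon-misaligned" (one increment
    straddling a horizon boundary 50/50), "no-roots-site" (a metadata-only
    site that must be excluded with a reason code).
    """
    if name == "perfect-1to1":
        return _fixture_tables([("P1", 0.2, 2.0), ("P2", 0.4, 4.0),
                                ("P3", 0.6, 6.0), ("P4", 0.8, 8.0)])
    if name == "all-accrual":
        ds = _fixture_tables([
            ("G1", 0.1, 20.0), ("G2", 0.2, 30.0), ("G3", 0.3, 40.0),
            ("F1", 0.1, 0.5), ("F2", 0.2, 10.0), ("F3", 0.3, 20.0)])
        ds.sites.loc[ds.sites["site_id"].str.startswith("F"), "ecosystem"] = "forest"
        return ds
    if name == "two-horizon-misaligned":
        ds = _fixture_tables([("M1", 0.1, 1.0)])
        ds.horizons = pd.DataFrame([
            {"site_id": "M1", "horizon_label": "M1", "top": 0.0, "bottom": 25.0,
             "is_organic": False, "oc_pct": 1.0, "bulk_density": 1.0,
             "clay_pct": 20.0},
            {"site_id": "M1", "horizon_label": "M2", "top": 25.0, "bottom": 50.0,
             "is_organic": False, "oc_pct": 0.5, "bulk_density": 1.2,
             "clay_pct": 25.0},
        ], columns=HORIZONS_HEADER)
        ds.roots = pd.DataFrame([
            {"site_id": "M1", "top": 20.0, "bottom": 30.0, "biomass": 100.0,
             "root_c_pct": 50.0, "status": "live", "diameter_protocol": "2mm"},
        ], columns=ROOTS_HEADER)
        return ds
    if name == "no-roots-site":
        ds = _fixture_tables([("R1", 0.2, 2.0), ("R2", 0.4, 4.0)])
        ds.roots = ds.roots[ds.roots["site_id"] != "R2"].reset_index(drop=True)
        return ds
    raise KeyError(f"unknown fixture {name!r}; known: perfect-1to1, all-accrual, "
                   "two-horizon-misaligned, no-roots-site")
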