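"""Flat-table I/O.

Reads the three harmonized input CSVs (``sites.csv``, ``horizons.csv``,
``roots.csv``), validates every row against the record invariants, and
serializes all derived products (layer stocks, beta estimates, accrual
records, model reports) with deterministic column order. Writing then
re-reading any numeric table is the identity (Python shortest-repr floats
round-trip exactly).

CSV dialect: comma-separated, UTF-8, "." decimal, empty cell = missing.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .records import (
    EXCL_NO_HORIZON_DATA,
    EXCL_NO_ROOT_DATA,
    RootIncrement,
    SchemaError,
    SiteMeta,
    SiteProfile,
    SoilHorizon,
    LayerStock,
    check_disjoint_sorted,
)

SITES_COLUMNS = ["site_id", "ecosystem", "mat", "map", "max_profile_depth", "litterfall"]
HORIZONS_COLUMNS = ["site_id", "horizon_label", "top", "bottom", "is_organic",
                    "oc_pct", "bulk_density", "clay_pct"]
ROOTS_COLUMNS = ["site_id", "top", "bottom", "biomass", "root_c_pct", "status",
                 "diameter_protocol"]
STOCKS_COLUMNS = ["site_id", "top", "bottom", "is_organic", "frc", "soc", "clay_pct"]
BETA_COLUMNS = ["site_id", "quantity", "beta", "sse", "n_points", "excluded", "reason"]
ACCRUAL_COLUMNS = ["site_id", "ecosystem", "depth_class", "z_frc", "z_soc",
                   "residual", "label"]
AGGREGATE_COLUMNS = [
    "site_id", "ecosystem", "frc_total", "soc_total", "frc_organic", "soc_organic",
    "frc_mineral", "soc_mineral", "frc_shallow", "soc_shallow", "frc_deep",
    "soc_deep", "aridity", "clay_whole", "clay_shallow", "clay_deep", "mat",
    "map_mm", "max_profile_depth", "litterfall", "has_organic",
]


def _check_schema(df: pd.DataFrame, columns: list[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(table, missing)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _as_bool(v) -> bool:
    if isinstance(v, (bool,)):
        return v
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def read_site_tables(sites_path, horizons_path, roots_path) -> list[SiteProfile]:
    """Read and validate the three input tables into SiteProfile skeletons.

    Sites present in the metadata but lacking root rows (or horizon rows)
    are returned flagged ``excluded`` with a machine-readable reason code,
    never dropped silently. Horizons and increments are checked for sorted,
    non-overlapping depth intervals per site.
    """
    return profiles_from_frames(_read_csv(sites_path), _read_csv(horizons_path),
                                _read_csv(roots_path))


def profiles_from_frames(sites_df: pd.DataFrame, horizons_df: pd.DataFrame,
                         roots_df: pd.DataFrame) -> list[SiteProfile]:
    """Validate in-memory input tables into SiteProfile skeletons (the
    DataFrame counterpart of :func:`read_site_tables`)."""
    _check_schema(sites_df, SITES_COLUMNS[:5], "sites")  # litterfall optional
    _check_schema(horizons_df, HORIZONS_COLUMNS, "horizons")
    _check_schema(roots_df, ROOTS_COLUMNS, "roots")

    horizons_by_site: dict[str, list[SoilHorizon]] = {}
    for _, r in horizons_df.iterrows():
        h = SoilHorizon(
            site_id=str(r["site_id"]),
            horizon_label=str(r["horizon_label"]),
            top=float(r["top"]), bottom=float(r["bottom"]),
            is_organic=_as_bool(r["is_organic"]),
            oc_pct=float(r["oc_pct"]),
            bulk_density=float(r["bulk_density"]),
            clay_pct=float(r["clay_pct"]),
        ).validate()
        horizons_by_site.setdefault(h.site_id, []).append(h)

    roots_by_site: dict[str, list[RootIncrement]] = {}
    for _, r in roots_df.iterrows():
        inc = RootIncrement(
            site_id=str(r["site_id"]),
            top=float(r["top"]), bottom=float(r["bottom"]),
            biomass=float(r["biomass"]),
            root_c_pct=float(r["root_c_pct"]),
            status=str(r["status"]),
            diameter_protocol=str(r["diameter_protocol"]),
        ).validate()
        roots_by_site.setdefault(inc.site_id, []).append(inc)

    for site_id, hs in horizons_by_site.items():
        hs.sort(key=lambda h: h.top)
        check_disjoint_sorted([(h.top, h.bottom) for h in hs], "horizons", site_id)
    for site_id, incs in roots_by_site.items():
        # live/dead rows may share a depth interval; disjointness applies
        # within a status class
        incs.sort(key=lambda i: (i.top, i.status))
        for status in ("live", "dead"):
            sub = [i for i in incs if i.status == status]
            check_disjoint_sorted([(i.top, i.bottom) for i in sub],
                                  f"{status} root increments", site_id)

    profiles = []
    for _, r in sites_df.iterrows():
        meta = SiteMeta(
            site_id=str(r["site_id"]),
            ecosystem=str(r["ecosystem"]),
            mat=float(r["mat"]),
            map_mm=float(r["map"]),
            max_profile_depth=float(r["max_profile_depth"]),
            litterfall=_opt_float(r.get("litterfall")),
        ).validate()
        p = SiteProfile(
            meta=meta,
            horizons=horizons_by_site.get(meta.site_id, []),
            increments=roots_by_site.get(meta.site_id, []),
        )
        if not p.increments:
            p.exclude(EXCL_NO_ROOT_DATA)
        elif not p.horizons:
            p.exclude(EXCL_NO_HORIZON_DATA)
        profiles.append(p)
    return profiles


# ---------------------------------------------------------------- writers

def write_sites(profiles: list[SiteProfile], path) -> None:
    rows = [{
        "site_id": p.meta.site_id, "ecosystem": p.meta.ecosystem,
        "mat": p.meta.mat, "map": p.meta.map_mm,
        "max_profile_depth": p.meta.max_profile_depth,
        "litterfall": p.meta.litterfall,
    } for p in profiles]
    pd.DataFrame(rows, columns=SITES_COLUMNS).to_csv(path, index=False)


def write_stocks(layers: list[LayerStock], path) -> None:
    rows = [{
        "site_id": l.site_id, "top": l.top, "bottom": l.bottom,
        "is_organic": l.is_organic, "frc": l.frc, "soc": l.soc,
        "clay_pct": l.clay_pct,
    } for l in layers]
    pd.DataFrame(rows, columns=STOCKS_COLUMNS).to_csv(path, index=False)


def read_stocks(path) -> list[LayerStock]:
    df = _read_csv(path)
    _check_schema(df, STOCKS_COLUMNS, "stocks")
    return [LayerStock(site_id=str(r["site_id"]), top=float(r["top"]),
                       bottom=float(r["bottom"]), is_organic=_as_bool(r["is_organic"]),
                       frc=float(r["frc"]), soc=float(r["soc"]),
                       clay_pct=float(r["clay_pct"])).validate()
            for _, r in df.iterrows()]


def write_beta(estimates, path) -> None:
    """Serialize BetaEstimate records (excluded rows keep their reason)."""
    rows = [{
        "site_id": e.site_id, "quantity": e.quantity,
        "beta": e.beta, "sse": e.sse, "n_points": e.n_points,
        "excluded": e.excluded, "reason": e.reason,
    } for e in estimates]
    pd.DataFrame(rows, columns=BETA_COLUMNS).to_csv(path, index=False)


def read_beta(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_schema(df, BETA_COLUMNS, "beta")
    return df


def write_accrual(records: pd.DataFrame, path) -> None:
    _check_schema(records, ACCRUAL_COLUMNS, "accrual")
    records.loc[:, ACCRUAL_COLUMNS].to_csv(path, index=False)


def read_accrual(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_schema(df, ACCRUAL_COLUMNS, "accrual")
    return df


def write_aggregates(aggregates, path) -> None:
    rows = [{c: getattr(a, "map_mm" if c == "map_mm" else c) for c in AGGREGATE_COLUMNS}
            for a in aggregates]
    pd.DataFrame(rows, columns=AGGREGATE_COLUMNS).to_csv(path, index=False)


def read_aggregates(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_schema(df, AGGREGATE_COLUMNS, "aggregates")
    return df


def write_models_report(report: dict, path) -> None:
    """Structured JSON report: candidate tables and selected fits."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")


def read_models_report(path) -> dict:
    return json.loads(Path(path).read_text())
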