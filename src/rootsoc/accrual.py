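"""Standardized 1:1-line residuals: inferred SOC accrual vs priming.

Within each depth class (shallow = above 30 cm, deep = below), per-site FRC
and SOC stocks are standardized to z-scores and compared against the
theoretical 1:1 line where one standardized unit of fine-root carbon input
corresponds to one standardized unit of soil organic carbon. The residual

    r = z_SOC - z_FRC

is the accrual/priming proxy: r > 0 (above the line) is inferred net SOC
accrual, r < 0 inferred net priming, r = 0 neutral. Residuals can then be
regressed on climate/texture covariates per ecosystem and depth class.

Standardization grouping defaults to pooling all sites within a depth
class (ecosystems share one 1:1 line); per-ecosystem grouping is available
via configuration. Sample (n-1) standard deviation throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import AnalysisConfig, DEFAULT_CONFIG
from .records import SiteAggregate, ValidationError

DEPTH_CLASSES = ("shallow", "deep")


class ZeroVarianceError(ValidationError):
    """A standardization group has no spread in one of its variables."""


def standardize(values, group: str = "group") -> np.ndarray:
    """z-scores with sample (n-1) sd; errors name the offending group."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError(f"standardization group {group!r} needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError(f"zero variance in standardization group {group!r}")
    return (x - x.mean()) / sd


#: residuals within this absolute band classify as neutral, so exact
#: on-the-line constructions are not relabelled by float rounding
NEUTRAL_ATOL = 1e-12


def classify_residual(residual: float) -> str:
    if residual > NEUTRAL_ATOL:
        return "accrual"
    if residual < -NEUTRAL_ATOL:
        return "priming"
    return "neutral"


def one_to_one_residuals(z_frc, z_soc, site_ids, ecosystems,
                         depth_class: str) -> pd.DataFrame:
    """AccrualRecord rows from paired standardized stocks."""
    z_frc = np.asarray(z_frc, dtype=float)
    z_soc = np.asarray(z_soc, dtype=float)
    if not (len(z_frc) == len(z_soc) == len(site_ids) == len(ecosystems)):
        raise ValidationError("unpaired inputs: all vectors must share length")
    resid = z_soc - z_frc
    return pd.DataFrame({
        "site_id": list(site_ids),
        "ecosystem": list(ecosystems),
        "depth_class": depth_class,
        "z_frc": z_frc,
        "z_soc": z_soc,
        "residual": resid,
        "label": [classify_residual(r) for r in resid],
    })


def build_accrual_records(aggregates: list[SiteAggregate],
                          config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Standardize per depth class and score every site against the 1:1 line.

    One row per site x depth class. Ecosystem tags are mapped to analysis
    classes (tundra folds into grassland by default) before any
    per-ecosystem grouping.
    """
    rows = []
    eco = [config.ecosystem_class(a.ecosystem) for a in aggregates]
    df = pd.DataFrame({
        "site_id": [a.site_id for a in aggregates],
        "ecosystem": eco,
        "frc_shallow": [a.frc_shallow for a in aggregates],
        "soc_shallow": [a.soc_shallow for a in aggregates],
        "frc_deep": [a.frc_deep for a in aggregates],
        "soc_deep": [a.soc_deep for a in aggregates],
    })
    if config.standardization == "pooled":
        groups = [("pooled", df)]
    else:
        # singleton ecosystems cannot be standardized within themselves and
        # are left out of the per-ecosystem 1:1 analysis
        groups = [(name, g) for name, g in df.groupby("ecosystem", sort=True)
                  if len(g) >= 2]
    for depth_class in DEPTH_CLASSES:
        for name, g in groups:
            zf = standardize(g[f"frc_{depth_class}"], f"{name}/{depth_class}/FRC")
            zs = standardize(g[f"soc_{depth_class}"], f"{name}/{depth_class}/SOC")
            rows.append(one_to_one_residuals(zf, zs, g["site_id"].tolist(),
                                             g["ecosystem"].tolist(), depth_class))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["depth_class", "site_id"], ignore_index=True)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> dict:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return {
        "slope": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "p": float(fit.pvalues[1]),
        "intercept": float(fit.params[0]),
        "n": int(len(y)),
    }


def depth_slope_contrast(records: pd.DataFrame, ecosystem: str,
                         min_n: int = 3) -> pd.DataFrame:
    """Per-depth-class OLS slope of z_SOC on z_FRC within one ecosystem.

    A slope above 1 in the deep class relative to shallow indicates more
    SOC per unit FRC at depth. Classes with fewer than `min_n` sites are
    returned excluded with a reason, not dropped.
    """
    out = []
    sub = records[records["ecosystem"] == ecosystem]
    for depth_class in DEPTH_CLASSES:
        g = sub[sub["depth_class"] == depth_class]
        if len(g) < min_n:
            out.append({"ecosystem": ecosystem, "depth_class": depth_class,
                        "slope": np.nan, "se": np.nan, "p": np.nan,
                        "intercept": np.nan, "n": int(len(g)),
                        "excluded": True, "reason": "insufficient_n"})
            continue
        d = _ols_slope(g["z_frc"].to_numpy(), g["z_soc"].to_numpy())
        d.update({"ecosystem": ecosystem, "depth_class": depth_class,
                  "excluded": False, "reason": None})
        out.append(d)
    return pd.DataFrame(out, columns=["ecosystem", "depth_class", "slope", "se",
                                      "p", "intercept", "n", "excluded", "reason"])


def _check_rank(X: pd.DataFrame) -> None:
    """Raise naming collinear columns when the design is rank deficient."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns whose removal restores full column rank
        collinear = [c for i, c in enumerate(X.columns)
                     if np.linalg.matrix_rank(np.delete(arr, i, axis=1)) == rank]
        raise ValidationError(
            f"rank-deficient design: collinear columns {collinear}")


def explain_residuals(records: pd.DataFrame, covariates: pd.DataFrame,
                      terms: list[str], min_n: int | None = None) -> dict:
    """Multiple regression of 1:1 residuals on site covariates, per
    ecosystem x depth class.

    `covariates` has one row per site_id with the covariate columns
    (typically aridity, MAP, clay, and a micronutrient proxy). Complete-case
    rows only. Returns, per group, coefficients with SEs and p-values,
    adjusted R^2, and n.
    """
    merged = records.merge(covariates, on="site_id", how="inner", validate="m:1")
    results = {}
    for (eco, depth_class), g in merged.groupby(["ecosystem", "depth_class"],
                                                sort=True):
        g = g.dropna(subset=["residual", *terms])
        need = (min_n if min_n is not None else len(terms) + 2)
        if len(g) < need:
            results[f"{eco}/{depth_class}"] = {
                "excluded": True, "reason": "insufficient_n", "n": int(len(g))}
            continue
        X = g[terms].astype(float)
        _check_rank(sm.add_constant(X))
        fit = sm.OLS(g["residual"].to_numpy(), sm.add_constant(X)).fit()
        results[f"{eco}/{depth_class}"] = {
            "excluded": False,
            "n": int(fit.nobs),
            "coefficients": {k: float(v) for k, v in fit.params.items()},
            "se": {k: float(v) for k, v in fit.bse.items()},
            "p_values": {k: float(v) for k, v in fit.pvalues.items()},
            "adj_r2": float(fit.rsquared_adj),
            "r2": float(fit.rsquared),
        }
    return results
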