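"""End-to-end orchestration: tables -> stocks -> beta -> accrual -> models.

Thin glue over the stage modules; every step is also usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import accrual as accrual_mod
from . import depthdist, io_tables, models, stocks
from .config import AnalysisConfig, DEFAULT_CONFIG
from .records import SiteProfile


@dataclass
class PipelineResult:
    layers: dict                      # site_id -> stocks.AlignmentResult
    aggregates: list                  # records.SiteAggregate
    beta: list                        # depthdist.BetaEstimate
    accrual: pd.DataFrame             # AccrualRecord rows
    exclusions: list = field(default_factory=list)  # (site_id, reason)

    @property
    def aggregate_frame(self) -> pd.DataFrame:
        rows = [{c: getattr(a, c) for c in io_tables.AGGREGATE_COLUMNS}
                for a in self.aggregates]
        return pd.DataFrame(rows, columns=io_tables.AGGREGATE_COLUMNS)

    @property
    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "site_id": e.site_id, "quantity": e.quantity, "beta": e.beta,
            "sse": e.sse, "n_points": e.n_points, "excluded": e.excluded,
            "reason": e.reason} for e in self.beta],
            columns=io_tables.BETA_COLUMNS)


def run_pipeline(profiles: list[SiteProfile],
                 config: AnalysisConfig = DEFAULT_CONFIG) -> PipelineResult:
    """Run alignment, aggregation, beta fitting and 1:1 residual scoring."""
    exclusions = [(p.site_id, p.exclusion_reason) for p in profiles if p.excluded]
    layer_map = stocks.site_layer_table(profiles, config)
    aggregates = stocks.aggregate_table(profiles, config)
    betas = depthdist.beta_table(
        {sid: res.layers for sid, res in layer_map.items()},
        min_points=config.min_points, bounds=config.beta_bounds)
    if len(aggregates) >= 2:
        acc = accrual_mod.build_accrual_records(aggregates, config)
    else:
        acc = pd.DataFrame(columns=io_tables.ACCRUAL_COLUMNS)
    return PipelineResult(layers=layer_map, aggregates=aggregates, beta=betas,
                          accrual=acc, exclusions=exclusions)


ANALYSES = ("whole", "organic", "mineral", "beta")

#: the full fixed-effect set for the stock analyses
FULL_FIXED = ("frc", "mat", "map", "clay_pct", "ecosystem")


def analysis_frame(aggregates: pd.DataFrame, analysis: str,
                   beta: pd.DataFrame | None = None,
                   config: AnalysisConfig = DEFAULT_CONFIG) -> tuple[pd.DataFrame, str]:
    """Model-ready frame for one analysis; returns (frame, response name).

    Generic column names: `frc` is the FRC quantity matched to the response
    (whole-profile, organic, mineral totals, or beta_frc), `map` is MAP,
    `clay_pct` the depth-weighted clay. `depth_bin` is the grouping factor
    for the random intercept. Ecosystem tags are mapped to analysis classes.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; one of {ANALYSES}")
    df = aggregates.copy()
    df["ecosystem"] = [config.ecosystem_class(e) for e in df["ecosystem"]]
    df["depth_bin"] = [models.depth_bin(d) for d in df["max_profile_depth"]]
    df["map"] = df["map_mm"]
    if analysis == "beta":
        if beta is None:
            raise ValueError("beta analysis needs the beta estimate table")
        ok = beta[~beta["excluded"].astype(bool)]
        wide = ok.pivot(index="site_id", columns="quantity", values="beta")
        wide = wide.rename(columns={"FRC": "beta_frc", "SOC": "beta_soc"})
        wide = wide.dropna(subset=["beta_frc", "beta_soc"]).reset_index()
        df = df.merge(wide, on="site_id", how="inner")
        df["frc"] = df["beta_frc"]
        response = "beta_soc"
        df["clay_pct"] = df["clay_whole"]
    else:
        part = {"whole": "total", "organic": "organic", "mineral": "mineral"}[analysis]
        if analysis == "organic":
            df = df[df["has_organic"].astype(bool)]
        df = df.copy()
        df["frc"] = df[f"frc_{part}"]
        response = f"soc_{part}"
        df["clay_pct"] = df["clay_whole"]
    return df.reset_index(drop=True), response


def run_models(aggregates: pd.DataFrame, analysis: str,
               beta: pd.DataFrame | None = None,
               fixed: tuple[str, ...] = FULL_FIXED,
               random: str | None = "depth_bin",
               config: AnalysisConfig = DEFAULT_CONFIG) -> dict:
    """Candidate-set fit and information-criterion selection for one
    analysis; result is JSON-serializable."""
    frame, response = analysis_frame(aggregates, analysis, beta, config)
    report = models.run_selection(frame, response, fixed, random)
    report["analysis"] = analysis
    return report
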