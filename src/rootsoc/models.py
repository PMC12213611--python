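"""Regression and mixed-effects model specification, fitting, and selection.

Site aggregates (whole-profile, organic-horizon, mineral-horizon stocks),
beta coefficients, and 1:1-line residuals are modelled against fine-root
carbon and climate/soil covariates. Specifications with a random term are
fit as linear mixed models with a random intercept for a maximum-profile-
depth bin; fixed-effects-only specifications are ordinary least squares.

Model selection follows an information-criterion rule: AICc when the data
set has fewer than 40 observations, AIC otherwise, with the full model
ineligible to win (guard against overparameterization) and deterministic
tie-breaking (fewer parameters, then lexicographic term order). Models
that differ in fixed effects are compared on maximum-likelihood fits;
reported mixed-model coefficients come from the REML fit. Mixed-model
fixed-effect p-values use the large-sample Wald normal approximation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import ValidationError

RESPONSES = ("soc_total", "soc_organic", "soc_mineral", "beta_soc", "residual")
FIXED_TERMS = ("frc", "mat", "map", "clay_pct", "ecosystem", "aridity", "litterfall")

#: bin edges turning continuous max profile depth (cm) into a grouping factor
DEPTH_BIN_EDGES = (100.0, 150.0)
AIC_SAMPLE_THRESHOLD = 40


def depth_bin(max_profile_depth: float) -> str:
    """Grouping factor for the random intercept: <=100, 100-150, >150 cm."""
    if max_profile_depth <= DEPTH_BIN_EDGES[0]:
        return "<=100"
    if max_profile_depth <= DEPTH_BIN_EDGES[1]:
        return "100-150"
    return ">150"


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed: tuple[str, ...]            # sorted term names; () = null model
    random: str | None = None         # grouping column, e.g. "depth_bin"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(sorted(self.fixed)))
        if self.response in self.fixed:
            raise ValidationError(f"response {self.response!r} cannot be a fixed term")

    @property
    def label(self) -> str:
        terms = "+".join(self.fixed) if self.fixed else "1"
        suffix = f" | {self.random}" if self.random else ""
        return f"{self.response} ~ {terms}{suffix}"


@dataclass(frozen=True)
class ModelFit:
    spec: ModelSpec
    coefficients: dict
    se: dict
    p_values: dict
    aic: float
    aicc: float                        # NaN when n <= k+1
    k: int                             # parameters counted in AIC (incl. variances)
    n: int
    llf: float                         # ML log-likelihood used for AIC
    adj_r2: float = math.nan           # OLS only
    marginal_pseudo_r2: float = math.nan  # mixed only
    variance_at_boundary: bool = False

    def criterion(self, n: int) -> float:
        return self.aicc if n < AIC_SAMPLE_THRESHOLD else self.aic

    def to_dict(self) -> dict:
        return {
            "model": self.spec.label,
            "fixed": list(self.spec.fixed),
            "random": self.spec.random,
            "coefficients": self.coefficients,
            "se": self.se,
            "p_values": self.p_values,
            "aic": self.aic,
            "aicc": self.aicc,
            "k": self.k,
            "n": self.n,
            "adj_r2": self.adj_r2,
            "marginal_pseudo_r2": self.marginal_pseudo_r2,
            "variance_at_boundary": self.variance_at_boundary,
        }


def aicc(aic: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: aic + 2k(k+1)/(n-k-1); undefined for
    n <= k+1."""
    if n <= k + 1:
        raise ValidationError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def design_matrix(data: pd.DataFrame, fixed: tuple[str, ...]) -> pd.DataFrame:
    """Intercept + numeric terms + treatment-coded categorical terms.

    Categorical levels are sorted so dummy order is deterministic; the
    first level is the reference.
    """
    cols = {"const": np.ones(len(data))}
    for term in fixed:
        col = data[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                cols[f"{term}[{lev}]"] = (col == lev).astype(float).to_numpy()
        else:
            cols[term] = col.astype(float).to_numpy()
    return pd.DataFrame(cols, index=data.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        collinear = [c for i, c in enumerate(X.columns)
                     if np.linalg.matrix_rank(np.delete(arr, i, axis=1)) == rank]
        raise ValidationError(f"rank-deficient design: collinear columns {collinear}")


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit one specification on complete-case rows.

    OLS when no random term; random-intercept linear mixed model otherwise.
    AIC is -2*llf + 2k with k counting regression coefficients plus
    variance components (+1 residual variance), matching the convention of
    R's ``AIC()`` so AICc composes consistently.
    """
    needed = [spec.response, *spec.fixed]
    if spec.random:
        needed.append(spec.random)
    rows = data.dropna(subset=[c for c in needed if c in data.columns])
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValidationError(f"data lacks columns {missing}")
    y = rows[spec.response].astype(float).to_numpy()
    X = design_matrix(rows, spec.fixed)
    _check_full_rank(X)
    n = len(rows)
    if n < X.shape[1] + 2:
        raise ValidationError(
            f"{spec.label}: n={n} too small for {X.shape[1]} parameters")

    if spec.random is None:
        fit = sm.OLS(y, X).fit()
        k = X.shape[1] + 1  # + residual variance
        aic = -2.0 * fit.llf + 2.0 * k
        return ModelFit(
            spec=spec,
            coefficients={c: float(v) for c, v in fit.params.items()},
            se={c: float(v) for c, v in fit.bse.items()},
            p_values={c: float(v) for c, v in fit.pvalues.items()},
            aic=aic,
            aicc=aicc(aic, k, n) if n > k + 1 else math.nan,
            k=k, n=n, llf=float(fit.llf),
            adj_r2=float(fit.rsquared_adj),
        )

    groups = rows[spec.random].astype(str).to_numpy()
    with warnings.catch_warnings():
        # boundary variance estimates trigger benign convergence/sqrt
        # warnings; the boundary case is reported via the flag below
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        reml = model.fit(reml=True)
        ml = model.fit(reml=False)
        coefficients = {c: float(v) for c, v in reml.fe_params.items()}
        se = {c: float(v) for c, v in reml.bse_fe.items()}
        p_values = {c: float(v) for c, v in reml.pvalues.items() if c in X.columns}
    k = X.shape[1] + 2  # + group variance + residual variance
    aic = -2.0 * float(ml.llf) + 2.0 * k
    var_group = float(np.asarray(reml.cov_re).ravel()[0])
    var_resid = float(reml.scale)
    fitted_fixed = X.to_numpy() @ reml.fe_params.to_numpy()
    var_fixed = float(np.var(fitted_fixed, ddof=0))
    denom = var_fixed + var_group + var_resid
    return ModelFit(
        spec=spec,
        coefficients=coefficients,
        se=se,
        p_values=p_values,
        aic=aic,
        aicc=aicc(aic, k, n) if n > k + 1 else math.nan,
        k=k, n=n, llf=float(ml.llf),
        marginal_pseudo_r2=var_fixed / denom if denom > 0 else math.nan,
        variance_at_boundary=var_group < 1e-8 * max(var_resid, 1e-12),
    )


def candidate_set(full_spec: ModelSpec) -> list[ModelSpec]:
    """Null model, full model, and every intermediate subset of fixed terms.

    All-subsets enumeration (2^t specs for t terms) guarantees any
    single-term-deletion path from the full model to the null is covered.
    Deterministic order: by term count, then lexicographic.
    """
    terms = full_spec.fixed
    specs = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(sorted(terms), r):
            specs.append(ModelSpec(full_spec.response, combo, full_spec.random))
    uniq = sorted(set(specs), key=lambda s: (len(s.fixed), s.fixed))
    return uniq


def select_model(fits: list[ModelFit], n: int,
                 full_spec: ModelSpec | None = None) -> ModelFit:
    """Pick the best-supported model by AICc (n < 40) or AIC.

    The full model (largest term set; inferred as the union of all fixed
    sets when not given) is ineligible, guarding against
    overparameterization. Ties break to fewer parameters, then to
    lexicographic term order.
    """
    if len(fits) < 2:
        raise ValidationError("select_model needs at least 2 fits")
    if full_spec is None:
        union = tuple(sorted({t for f in fits for t in f.spec.fixed}))
        full_candidates = [f.spec for f in fits if f.spec.fixed == union]
        full_spec = full_candidates[0] if full_candidates else None
    eligible = [f for f in fits if full_spec is None or f.spec != full_spec]
    eligible = [f for f in eligible if math.isfinite(f.criterion(n))]
    if not eligible:
        raise ValidationError("no eligible fits to select from")
    return min(eligible, key=lambda f: (f.criterion(n), f.k, f.spec.fixed))


def run_selection(data: pd.DataFrame, response: str, fixed: tuple[str, ...],
                  random: str | None = None) -> dict:
    """Candidate table + selected fit for one analysis; JSON-serializable."""
    full = ModelSpec(response, fixed, random)
    specs = candidate_set(full)
    fits, failed = [], []
    for s in specs:
        try:
            fits.append(fit_model(s, data))
        except (ValidationError, np.linalg.LinAlgError) as exc:
            failed.append({"model": s.label, "error": str(exc)})
    if not fits:
        raise ValidationError("all candidate fits failed")
    n = max(f.n for f in fits)
    best = select_model(fits, n, full_spec=full)
    return {
        "response": response,
        "n": n,
        "criterion": "AICc" if n < AIC_SAMPLE_THRESHOLD else "AIC",
        "candidates": [
            {"model": f.spec.label, "k": f.k, "aic": f.aic, "aicc": f.aicc}
            for f in fits
        ],
        "failed": failed,
        "selected": best.to_dict(),
        "full": next(f.to_dict() for f in fits if f.spec == full)
        if any(f.spec == full for f in fits) else None,
    }


def diameter_protocol_check(residuals, protocols) -> tuple[float, float]:
    """Rank-sum comparison of FRC-SOC residuals between the 2-mm and 4-mm
    root-diameter protocols.

    Returns (z, p): z is the normal-approximation rank-sum statistic
    (tie-corrected), p is the two-sided Mann-Whitney p-value (exact for
    small tie-free samples). A non-significant result supports pooling the
    two protocols.
    """
    residuals = np.asarray(residuals, dtype=float)
    protocols = np.asarray(protocols)
    x = residuals[protocols == "2mm"]
    y = residuals[protocols == "4mm"]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both diameter-protocol groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    nn = n1 + n2
    tie_term = float(np.sum(counts ** 3 - counts)) / (nn * (nn - 1)) if nn > 1 else 0.0
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term)
    z = 0.0 if var == 0 else (float(res.statistic) - mu) / math.sqrt(var)
    return z, float(res.pvalue)
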