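"""Standardization, 1:1-line residuals, and residual regressions."""

import numpy as np
import pandas as pd
import pytest

from rootsoc.accrual import (
    ZeroVarianceError,
    build_accrual_records,
    depth_slope_contrast,
    explain_residuals,
    one_to_one_residuals,
    standardize,
)
from rootsoc.records import ValidationError
from rootsoc.synth import generate_standardized_depth_cohort, make_fixture
from rootsoc import io_tables, pipeline


def test_standardize_hand_example():
    z = standardize([1.0, 2.0, 3.0])
    assert z == pytest.approx([-1.0, 0.0, 1.0])  # sample sd = 1


def test_standardize_constant_vector_errors():
    with pytest.raises(ZeroVarianceError, match="shallow"):
        standardize([2.0, 2.0, 2.0], group="shallow")


def test_standardize_moments(rng):
    z = standardize(rng.normal(5, 3, size=40))
    assert abs(z.mean()) < 1e-9
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestResiduals:
    def test_on_line_all_neutral(self):
        z = np.array([-1.0, 0.0, 1.0])
        rec = one_to_one_residuals(z, z, ["a", "b", "c"], ["forest"] * 3, "shallow")
        assert (rec["residual"] == 0).all()
        assert (rec["label"] == "neutral").all()

    def test_above_line_is_accrual(self):
        rec = one_to_one_residuals([0.5], [1.5], ["a"], ["grassland"], "deep")
        assert rec.loc[0, "residual"] == pytest.approx(1.0)
        assert rec.loc[0, "label"] == "accrual"

    def test_swap_negates(self, rng):
        zf, zs = rng.normal(size=8), rng.normal(size=8)
        ids, eco = list("abcdefgh"), ["forest"] * 8
        r1 = one_to_one_residuals(zf, zs, ids, eco, "shallow")["residual"]
        r2 = one_to_one_residuals(zs, zf, ids, eco, "shallow")["residual"]
        assert np.allclose(r1, -r2)

    def test_unpaired_inputs_error(self):
        with pytest.raises(ValidationError):
            one_to_one_residuals([0.1], [0.2, 0.3], ["a"], ["forest"], "deep")


class TestGroupIdentities:
    def test_residuals_sum_to_zero_per_group(self, default_profiles):
        res = pipeline.run_pipeline(default_profiles)
        for depth_class, g in res.accrual.groupby("depth_class"):
            assert abs(g["residual"].sum()) < 1e-9

    def test_affine_rescaling_invariance(self, rng):
        """Common affine rescaling of raw stocks before standardization
        leaves the accrual/priming partition unchanged."""
        frc = rng.uniform(0.1, 1.0, size=12)
        soc = rng.uniform(2, 30, size=12)
        z1 = standardize(frc), standardize(soc)
        z2 = standardize(3.7 * frc + 1.2), standardize(0.5 * soc + 4.0)
        r1 = z1[1] - z1[0]
        r2 = z2[1] - z2[0]
        assert np.allclose(r1, r2, atol=1e-9)

    def test_perfect_1to1_fixture_all_neutral(self):
        ds = make_fixture("perfect-1to1")
        profiles = io_tables.profiles_from_frames(ds.sites, ds.horizons, ds.roots)
        res = pipeline.run_pipeline(profiles)
        assert np.allclose(res.accrual["residual"], 0.0, atol=1e-9)
        assert (res.accrual["label"] == "neutral").all()

    def test_all_accrual_fixture_partitions_by_ecosystem(self):
        ds = make_fixture("all-accrual")
        profiles = io_tables.profiles_from_frames(ds.sites, ds.horizons, ds.roots)
        res = pipeline.run_pipeline(profiles)
        grass = res.accrual[res.accrual["ecosystem"] == "grassland"]
        forest = res.accrual[res.accrual["ecosystem"] == "forest"]
        assert (grass["label"] == "accrual").all()
        assert (forest["label"] == "priming").all()


class TestDepthSlopeContrast:
    def test_exact_collinear_slope_one(self):
        z = np.linspace(-1.5, 1.5, 10)
        rec = one_to_one_residuals(z, z, [f"s{i}" for i in range(10)],
                                   ["grassland"] * 10, "deep")
        rec2 = rec.copy()
        rec2["depth_class"] = "shallow"
        table = depth_slope_contrast(pd.concat([rec, rec2]), "grassland")
        assert table["slope"].to_numpy() == pytest.approx([1.0, 1.0])
        assert (table["p"] < 1e-10).all()

    def test_slope_matches_normal_equations_oracle(self, rng):
        rec = generate_standardized_depth_cohort(20, rng)
        table = depth_slope_contrast(rec, "grassland")
        for depth_class in ("shallow", "deep"):
            g = rec[rec["depth_class"] == depth_class]
            X = np.column_stack([np.ones(len(g)), g["z_frc"]])
            beta = np.linalg.solve(X.T @ X, X.T @ g["z_soc"].to_numpy())
            got = table.set_index("depth_class").loc[depth_class, "slope"]
            assert got == pytest.approx(beta[1], abs=1e-10)

    def test_insufficient_n_excluded(self):
        rec = generate_standardized_depth_cohort(2, np.random.default_rng(0))
        table = depth_slope_contrast(rec, "grassland", min_n=3)
        assert table["excluded"].all()
        assert (table["reason"] == "insufficient_n").all()

    def test_null_coupling_ci_covers_zero(self, rng):
        """With no FRC-SOC coupling the slope CI straddles 0 about 95% of
        the time."""
        from scipy import stats
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            rec = generate_standardized_depth_cohort(
                15, rng, deep_slope=0.0, shallow_slope=0.0, noise_sd=1.0)
            row = depth_slope_contrast(rec, "grassland").iloc[0]
            tcrit = stats.t.ppf(0.975, row["n"] - 2)
            if abs(row["slope"]) <= tcrit * row["se"]:
                hits += 1
        assert 0.90 <= hits / n_rep <= 0.99


class TestExplainResiduals:
    def _records(self, residuals, eco="grassland"):
        n = len(residuals)
        return pd.DataFrame({
            "site_id": [f"s{i}" for i in range(n)],
            "ecosystem": eco, "depth_class": "shallow",
            "z_frc": 0.0, "z_soc": residuals, "residual": residuals,
            "label": ["accrual" if r > 0 else "priming" for r in residuals]})

    def test_zero_noise_linear_residuals_r2_one(self, rng):
        aridity = rng.uniform(10, 120, size=12)
        clay = rng.uniform(5, 40, size=12)
        resid = 0.02 * aridity - 0.01 * clay - 1.0
        cov = pd.DataFrame({"site_id": [f"s{i}" for i in range(12)],
                            "aridity": aridity, "clay_pct": clay})
        out = explain_residuals(self._records(resid), cov, ["aridity", "clay_pct"])
        fit = out["grassland/shallow"]
        assert fit["adj_r2"] == pytest.approx(1.0, abs=1e-8)
        assert fit["coefficients"]["aridity"] == pytest.approx(0.02, abs=1e-8)

    def test_aridity_coefficient_ci_coverage(self, rng):
        """95% CI covers the generating aridity coefficient ~95% of sims."""
        from scipy import stats
        true = 0.02
        hits, n_rep, n = 0, 200, 15
        for _ in range(n_rep):
            aridity = rng.uniform(10, 120, size=n)
            resid = true * aridity - 1.3 + rng.normal(0, 0.4, size=n)
            cov = pd.DataFrame({"site_id": [f"s{i}" for i in range(n)],
                                "aridity": aridity})
            fit = explain_residuals(self._records(resid), cov, ["aridity"])[
                "grassland/shallow"]
            tcrit = stats.t.ppf(0.975, fit["n"] - 2)
            lo = fit["coefficients"]["aridity"] - tcrit * fit["se"]["aridity"]
            hi = fit["coefficients"]["aridity"] + tcrit * fit["se"]["aridity"]
            hits += lo <= true <= hi
        assert 0.90 <= hits / n_rep <= 0.99

    def test_permuted_covariates_near_zero_r2(self, rng):
        r2s = []
        for _ in range(50):
            aridity = rng.uniform(10, 120, size=20)
            resid = 0.05 * aridity - 3 + rng.normal(0, 0.3, size=20)
            cov = pd.DataFrame({"site_id": [f"s{i}" for i in range(20)],
                                "aridity": rng.permutation(aridity)})
            fit = explain_residuals(self._records(resid), cov, ["aridity"])[
                "grassland/shallow"]
            r2s.append(fit["adj_r2"])
        assert abs(np.median(r2s)) < 0.15

    def test_collinear_covariates_named(self, rng):
        aridity = rng.uniform(10, 120, size=10)
        cov = pd.DataFrame({"site_id": [f"s{i}" for i in range(10)],
                            "aridity": aridity, "aridity2": 2 * aridity})
        with pytest.raises(ValidationError, match="aridity"):
            explain_residuals(self._records(rng.normal(size=10)), cov,
                              ["aridity", "aridity2"])


def test_by_ecosystem_grouping_standardizes_within_ecosystem(default_profiles):
    from rootsoc.config import AnalysisConfig
    from rootsoc import stocks as stocks_mod
    aggs = stocks_mod.aggregate_table(default_profiles)
    rec = build_accrual_records(aggs, AnalysisConfig(standardization="by-ecosystem"))
    for (eco, depth_class), g in rec.groupby(["ecosystem", "depth_class"]):
        assert abs(g["z_frc"].mean()) < 1e-9
        assert g["z_frc"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
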