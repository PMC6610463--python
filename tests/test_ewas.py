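"""EWAS designs: design-matrix construction, OLS against normal-equation
oracles, type-I error calibration, and mixed-model recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from methlung.ewas import (ModelSpec, annual_change, build_design,
                           cross_sectional_ewas, prediction_ewas,
                           repeat_ewas)


def _resid_df(m, samples):
    return pd.DataFrame(m, index=[f"p{i}" for i in range(m.shape[0])],
                        columns=samples)


class TestBuildDesign:
    def test_base_model_column_enumeration(self, toy_phenotypes):
        ph, cf = toy_phenotypes
        x = build_design(ph, cf, ModelSpec(model="base"))
        assert x.shape[1] == 22
        expected = {"const", "age", "age_sq", "height", "height_dev_sq",
                    "sex", "sex_x_age", "sex_x_age_sq", "sex_x_height",
                    "sex_x_height_dev_sq", "edu_intermediate", "edu_high",
                    "bmi", "spirometer_sp2", "centre_c2"}
        assert expected <= set(x.columns)
        assert sum(c.startswith("cell_") for c in x.columns) == 7

    def test_smoking_model_adds_three_columns(self, toy_phenotypes):
        ph, cf = toy_phenotypes
        x = build_design(ph, cf, ModelSpec(model="smok"))
        assert x.shape[1] == 25
        assert {"smoke_ex", "smoke_current", "pack_years"} <= set(x.columns)

    def test_interactions_are_elementwise_products(self, toy_phenotypes):
        ph, cf = toy_phenotypes
        x = build_design(ph, cf, ModelSpec())
        np.testing.assert_allclose(x["sex_x_age"], x["sex"] * x["age"])
        np.testing.assert_allclose(x["sex_x_height_dev_sq"],
                                   x["sex"] * x["height_dev_sq"])

    def test_single_centre_drops_column_without_error(self, toy_phenotypes):
        ph, cf = toy_phenotypes
        ph = ph.assign(centre="only")
        x = build_design(ph, cf, ModelSpec())
        assert not any(c.startswith("centre") for c in x.columns)

    def test_height_deviation_uses_analysis_sample_mean(self,
                                                        toy_phenotypes):
        ph, cf = toy_phenotypes
        sub = ph.iloc[:40]
        x = build_design(sub, cf, ModelSpec())
        expected = (sub["height"] - sub["height"].mean()) ** 2
        np.testing.assert_allclose(x["height_dev_sq"], expected)

    def test_smoking_model_in_never_smokers_is_rejected(self,
                                                        toy_phenotypes):
        with pytest.raises(ValueError, match="never"):
            ModelSpec(model="smok", population="never_smokers")
        ph, cf = toy_phenotypes
        only_never = ph[ph["smoking_status"] == "never"]
        with pytest.raises(ValueError, match="smoking"):
            build_design(only_never, cf, ModelSpec(model="smok"))

    def test_full_column_rank(self, toy_phenotypes):
        ph, cf = toy_phenotypes
        x = build_design(ph, cf, ModelSpec(model="smok"))
        assert np.linalg.matrix_rank(x.to_numpy()) == x.shape[1]


class TestCrossSectional:
    def test_exact_fit_recovers_coefficient(self):
        rng = np.random.default_rng(0)
        n = 50
        samples = [f"s{i}" for i in range(n)]
        m = rng.normal(size=(1, n))
        y = pd.Series(2.5 * m[0], index=samples)
        design = pd.DataFrame({"const": np.ones(n)}, index=samples)
        res = cross_sectional_ewas(_resid_df(m, samples), y, design)
        assert abs(res.loc["p0", "beta"] - 2.5) < 1e-10
        assert res.loc["p0", "p"] > 0          # underflow-safe minimum

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n, k = 30, 5
        samples = [f"s{i}" for i in range(n)]
        x = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        m = rng.normal(size=(3, n))
        y = rng.normal(size=n)
        design = pd.DataFrame(x, index=samples,
                              columns=[f"c{j}" for j in range(k)])
        res = cross_sectional_ewas(_resid_df(m, samples),
                                   pd.Series(y, index=samples), design)
        for i in range(3):
            full = np.column_stack([x, m[i]])
            xtx_inv = np.linalg.inv(full.T @ full)
            coef = xtx_inv @ full.T @ y
            rss = float((y - full @ coef) @ (y - full @ coef))
            se = np.sqrt(rss / (n - k - 1) * xtx_inv[-1, -1])
            assert abs(res.iloc[i]["beta"] - coef[-1]) < 1e-8
            assert abs(res.iloc[i]["se"] - se) < 1e-8

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        n = 200
        samples = [f"s{i}" for i in range(n)]
        design = pd.DataFrame(
            np.column_stack([np.ones(n), rng.normal(size=(n, 4))]),
            index=samples, columns=["const", "a", "b", "c", "d"])
        m = rng.normal(size=(2000, n))
        y = pd.Series(rng.normal(size=n), index=samples)
        res = cross_sectional_ewas(_resid_df(m, samples), y, design)
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_sign_equivariance(self):
        rng = np.random.default_rng(3)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        m = rng.normal(size=(5, n))
        y = pd.Series(rng.normal(size=n), index=samples)
        design = pd.DataFrame(
            np.column_stack([np.ones(n), rng.normal(size=n)]),
            index=samples, columns=["const", "z"])
        base = cross_sectional_ewas(_resid_df(m, samples), y, design)
        neg_y = cross_sectional_ewas(_resid_df(m, samples), -y, design)
        neg_m = cross_sectional_ewas(_resid_df(-m, samples), y, design)
        np.testing.assert_allclose(base["beta"], -neg_y["beta"], atol=1e-12)
        np.testing.assert_allclose(base["beta"], -neg_m["beta"], atol=1e-12)

    def test_orthogonal_covariate_leaves_coefficient_unchanged(self):
        rng = np.random.default_rng(4)
        n = 64
        samples = [f"s{i}" for i in range(n)]
        m = rng.normal(size=(1, n))
        y = pd.Series(1.7 * m[0], index=samples)
        extra = rng.normal(size=n)
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), m[0], y]))
        extra = extra - q @ (q.T @ extra)      # orthogonal to all
        d1 = pd.DataFrame({"const": np.ones(n)}, index=samples)
        d2 = d1.assign(extra=extra)
        r1 = cross_sectional_ewas(_resid_df(m, samples), y, d1)
        r2 = cross_sectional_ewas(_resid_df(m, samples), y, d2)
        assert abs(r1.loc["p0", "beta"] - r2.loc["p0", "beta"]) < 1e-8

    def test_zero_variance_probe_skipped(self):
        n = 30
        samples = [f"s{i}" for i in range(n)]
        m = np.vstack([np.full(n, 0.3), np.random.default_rng(5).normal(
            size=n)])
        y = pd.Series(np.random.default_rng(6).normal(size=n),
                      index=samples)
        design = pd.DataFrame({"const": np.ones(n)}, index=samples)
        res = cross_sectional_ewas(_resid_df(m, samples), y, design)
        assert "p0" not in res.index and "p1" in res.index


class TestAnnualChange:
    def test_arithmetic(self):
        assert annual_change(4.0, 3.5, 10.0) == pytest.approx(-0.05)
        assert annual_change(3.0, 3.0, 8.0) == 0.0

    def test_vectorized_equals_scalar(self):
        rng = np.random.default_rng(7)
        lf1 = rng.uniform(2, 5, 100)
        lf2 = rng.uniform(2, 5, 100)
        fu = rng.uniform(6, 15, 100)
        vec = annual_change(lf1, lf2, fu)
        scalar = np.array([annual_change(a, b, f)
                           for a, b, f in zip(lf1, lf2, fu)])
        np.testing.assert_allclose(vec, scalar)

    def test_nonpositive_follow_up_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            annual_change(4.0, 3.5, 0.0)


class TestPrediction:
    def _setup(self, rng, n, signal):
        samples = [f"s{i}" for i in range(n)]
        m = rng.normal(size=(1, n))
        fu = pd.Series(rng.uniform(6, 15, n), index=samples)
        lf1 = pd.Series(rng.uniform(3, 5, n), index=samples)
        change = signal * m[0] + rng.normal(0, 0.05, n)
        lf2 = lf1 + change * fu
        design = pd.DataFrame({"const": np.ones(n)}, index=samples)
        return _resid_df(m, samples), lf1, lf2, fu, design

    def test_recovers_change_slope(self):
        rng = np.random.default_rng(8)
        resid, lf1, lf2, fu, design = self._setup(rng, 500, signal=0.02)
        res = prediction_ewas(resid, lf1, lf2, fu, design)
        assert abs(res.loc["p0", "beta"] - 0.02) < 2 * res.loc["p0", "se"]

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(9)
        n = 150
        samples = [f"s{i}" for i in range(n)]
        m = rng.normal(size=(2000, n))
        fu = pd.Series(rng.uniform(6, 15, n), index=samples)
        lf1 = pd.Series(rng.uniform(3, 5, n), index=samples)
        lf2 = lf1 + rng.normal(0, 0.3, n)
        design = pd.DataFrame({"const": np.ones(n)}, index=samples)
        res = prediction_ewas(_resid_df(m, samples), lf1, lf2, fu, design)
        assert kstest(res["p"], "uniform").pvalue > 0.01

    def test_baseline_column_added_exactly_once(self):
        rng = np.random.default_rng(10)
        resid, lf1, lf2, fu, design = self._setup(rng, 50, signal=0.0)
        res = prediction_ewas(resid, lf1, lf2, fu, design)
        assert res.attrs["design_columns"].count("baseline_lf") == 1
        with pytest.raises(ValueError, match="baseline_lf"):
            prediction_ewas(resid, lf1, lf2, fu,
                            design.assign(baseline_lf=lf1))


class TestRepeat:
    def _panel_data(self, rng, n_subj, icc_sd, resid_sd, slope=0.5):
        subjects = [f"p{i}" for i in range(n_subj)]
        samples = [f"{p}_t{t}" for p in subjects for t in (1, 2)]
        groups = pd.Series([s.rsplit("_", 1)[0] for s in samples],
                           index=samples)
        m = rng.normal(size=2 * n_subj)
        u = np.repeat(rng.normal(0, icc_sd, n_subj), 2)
        y = pd.Series(slope * m + u + rng.normal(0, resid_sd, 2 * n_subj),
                      index=samples)
        design = pd.DataFrame({"const": np.ones(2 * n_subj)}, index=samples)
        resid = pd.DataFrame([m], index=["p0"], columns=samples)
        return resid, y, design, groups

    def test_zero_variance_reduces_to_pooled_ols(self):
        rng = np.random.default_rng(11)
        resid, y, design, groups = self._panel_data(rng, 100, 0.0, 1.0)
        res = repeat_ewas(resid, y, design, groups)
        x = np.column_stack([np.ones(len(y)), resid.loc["p0"]])
        ols = np.linalg.lstsq(x, y.to_numpy(), rcond=None)[0][1]
        assert abs(res.loc["p0", "beta"] - ols) < 1e-6

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(12)
        resid, y, design, groups = self._panel_data(rng, 500, 1.0, 1.0)
        import statsmodels.api as sm
        exog = np.column_stack([np.ones(len(y)), resid.loc["p0"]])
        fit = sm.MixedLM(y.to_numpy(), exog,
                         groups=groups.to_numpy()).fit(reml=True)
        ratio = float(np.asarray(fit.cov_re)[0, 0]) / float(fit.scale)
        assert 0.8 <= ratio <= 1.25

    def test_matches_known_variance_gls_oracle(self):
        rng = np.random.default_rng(13)
        n_subj = 200
        resid, y, design, groups = self._panel_data(rng, n_subj, 1.0, 1.0)
        res = repeat_ewas(resid, y, design, groups)
        # GLS with the true variance components plugged in
        x = np.column_stack([np.ones(2 * n_subj), resid.loc["p0"]])
        blocks = np.array([[2.0, 1.0], [1.0, 2.0]])   # sigma_u=sigma_e=1
        vinv_block = np.linalg.inv(blocks)
        xtvx = np.zeros((2, 2))
        xtvy = np.zeros(2)
        yv = y.to_numpy()
        for i in range(n_subj):
            sl = slice(2 * i, 2 * i + 2)
            xtvx += x[sl].T @ vinv_block @ x[sl]
            xtvy += x[sl].T @ vinv_block @ yv[sl]
        gls = np.linalg.solve(xtvx, xtvy)
        gls_se = np.sqrt(np.linalg.inv(xtvx)[1, 1])
        assert abs(res.loc["p0", "beta"] - gls[1]) < 0.5 * gls_se

    def test_more_than_two_records_rejected(self):
        rng = np.random.default_rng(14)
        resid, y, design, groups = self._panel_data(rng, 10, 1.0, 1.0)
        bad_groups = groups.copy()
        bad_groups.iloc[:] = "same"
        with pytest.raises(ValueError, match="two records"):
            repeat_ewas(resid, y, design, bad_groups)
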