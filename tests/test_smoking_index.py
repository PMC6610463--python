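"""Smoking-index construction, association, variance decomposition and
adjusted group distributions, including recovery on synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from methlung.pipeline import index_run, mediation_cpg_set
from methlung.smoking_index import (CpGSet, adjusted_group_distribution,
                                    build_index, index_association,
                                    variance_decomposition)


def _residuals(rng, n_probes, n_samples):
    return pd.DataFrame(rng.normal(size=(n_probes, n_samples)),
                        index=[f"cg{i}" for i in range(n_probes)],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestBuildIndex:
    def test_uniform_one_sd_hypomethylation_scores_one(self):
        rng = np.random.default_rng(0)
        res = _residuals(rng, 10, 50)
        # plant a subject exactly 1 SD below each probe mean
        target = "s0"
        for probe in res.index:
            mu = res.loc[probe].drop(target).mean()
            sd = res.loc[probe].drop(target).std(ddof=0)
            res.loc[probe, target] = mu - sd
        cpg_set = CpGSet(list(res.index), ["-"] * 10)
        idx = build_index(res, cpg_set)
        # z-scoring includes the planted subject, so allow small slack
        assert idx.scores[target] == pytest.approx(1.0, abs=0.05)

    def test_sign_flip_negates_scores(self):
        rng = np.random.default_rng(1)
        res = _residuals(rng, 6, 30)
        neg = build_index(res, CpGSet(list(res.index), ["-"] * 6))
        pos = build_index(res, CpGSet(list(res.index), ["+"] * 6))
        np.testing.assert_allclose(neg.scores, -pos.scores, atol=1e-12)

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(2)
        res = _residuals(rng, 8, 20)
        ids = list(res.index)
        signs = ["-", "+"] * 4
        a = build_index(res, CpGSet(ids, signs))
        perm = np.random.default_rng(3).permutation(8)
        b = build_index(res, CpGSet([ids[i] for i in perm],
                                    [signs[i] for i in perm]))
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_out_of_sample_scoring_consistent(self):
        rng = np.random.default_rng(4)
        res = _residuals(rng, 5, 40)
        idx = build_index(res, CpGSet(list(res.index), ["-"] * 5))
        rescored = idx.score_new(res)
        np.testing.assert_allclose(rescored, idx.scores, atol=1e-12)

    def test_too_many_missing_probes_rejected(self):
        rng = np.random.default_rng(5)
        res = _residuals(rng, 3, 20)
        cpg_set = CpGSet([f"cg{i}" for i in range(8)], ["-"] * 8)
        with pytest.raises(ValueError, match="present"):
            build_index(res, cpg_set)

    def test_smoking_gradient_on_synthetic_cohort(self, study, prep):
        """Score ordering never < ex < current, and monotone in pack-year
        quartiles among current smokers."""
        cpg_set = mediation_cpg_set(study["effects"])
        ph = prep["phenotypes"]
        ph2 = ph[ph["timepoint"] == 2]
        idx = build_index(prep["residuals"][list(ph2.index)], cpg_set)
        means = idx.scores.groupby(ph2["smoking_status"]).mean()
        assert means["never"] < means["ex"] < means["current"]
        cur = ph2[ph2["smoking_status"] == "current"]
        quart = pd.qcut(cur["pack_years"], 4, labels=False)
        qmeans = idx.scores[cur.index].groupby(quart).mean()
        assert qmeans.is_monotonic_increasing


class TestAssociation:
    def _entry(self, rng, n, effect):
        samples = [f"s{j}" for j in range(n)]
        idx = pd.Series(rng.normal(size=n), index=samples)
        design = pd.DataFrame({"const": np.ones(n),
                               "age": rng.uniform(40, 60, n)},
                              index=samples)
        y = pd.Series(effect * idx + rng.normal(0, 1, n), index=samples)
        return dict(cohort_id="A", index=idx, outcome=y, design=design)

    def test_permuted_index_is_null(self):
        rng = np.random.default_rng(6)
        entry = self._entry(rng, 400, effect=0.5)
        perm = entry["index"].sample(frac=1.0, random_state=1)
        perm.index = entry["index"].index
        entry["index"] = perm
        res = index_association([entry], "all", "cross_sectional_t2")
        assert abs(res.iloc[0]["beta"]) < 2 * res.iloc[0]["se"]

    def test_single_cohort_meta_identity(self):
        rng = np.random.default_rng(7)
        entry = self._entry(rng, 200, effect=-0.4)
        res = index_association([entry], "all", "cross_sectional_t2")
        from methlung.smoking_index import _index_regression
        beta, se, n = _index_regression(entry["index"], entry["outcome"],
                                        entry["design"])
        assert res.iloc[0]["beta"] == pytest.approx(beta, abs=1e-12)
        assert res.iloc[0]["se"] == pytest.approx(se, abs=1e-12)

    def test_synthetic_mediated_effect_detected(self, study):
        """Index negatively associated with FEV1/FVC in all and ever
        strata; attenuated toward zero in never-smokers."""
        from methlung.pipeline import prepare_cohort
        preps = {cid: prepare_cohort(ds, study["panel"], n_pcs=20)
                 for cid, ds in study["cohorts"].items()}
        out = index_run(preps, mediation_cpg_set(study["effects"]))
        a = out["associations"]
        b_all = a[("cross_sectional_t2", "all")].iloc[0]
        b_ever = a[("cross_sectional_t2", "ever")].iloc[0]
        b_never = a[("cross_sectional_t2", "never")].iloc[0]
        assert b_all["beta"] < 0 and b_all["p"] < 1e-4
        assert b_ever["beta"] < 0
        assert abs(b_never["beta"]) < abs(b_all["beta"])


class TestVarianceDecomposition:
    def _design(self, rng, n):
        samples = [f"s{j}" for j in range(n)]
        return pd.DataFrame(
            {"const": np.ones(n), "x1": rng.normal(size=n),
             "x2": rng.normal(size=n)}, index=samples)

    def test_orthogonal_index_adds_nothing(self):
        rng = np.random.default_rng(8)
        n = 1000
        design = self._design(rng, n)
        y = pd.Series(design["x1"] + rng.normal(0, 1, n),
                      index=design.index)
        idx = pd.Series(rng.normal(size=n), index=design.index)
        smok = pd.DataFrame({"pack_years": rng.uniform(0, 30, n)},
                            index=design.index)
        table = variance_decomposition(y, design, idx, smok)
        assert abs(table.loc["M_base+index", "increment"]) < 0.002

    def test_known_partial_r2_recovered(self):
        target = 0.03
        increments = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 1500
            design = self._design(rng, n)
            idx = pd.Series(rng.normal(size=n), index=design.index)
            base_sig = design["x1"].to_numpy()
            # scale index contribution for partial R^2 = target
            var_rest = 1.0 + 1.0        # base signal + noise variance
            c = np.sqrt(target / (1 - target) * var_rest)
            y = pd.Series(base_sig + c * idx + rng.normal(0, 1, n),
                          index=design.index)
            smok = pd.DataFrame({"z": rng.normal(size=n)},
                                index=design.index)
            table = variance_decomposition(y, design, idx, smok)
            increments.append(table.loc["M_base+index", "increment"])
        assert 0.02 <= float(np.median(increments)) <= 0.04

    def test_adjusted_r2_formula_oracle(self):
        rng = np.random.default_rng(9)
        n = 60
        design = self._design(rng, n)
        y = pd.Series(design["x1"] * 0.5 + rng.normal(0, 1, n),
                      index=design.index)
        idx = pd.Series(rng.normal(size=n), index=design.index)
        smok = pd.DataFrame({"z": rng.normal(size=n)}, index=design.index)
        table = variance_decomposition(y, design, idx, smok)
        x = design.to_numpy()
        coef = np.linalg.lstsq(x, y.to_numpy(), rcond=None)[0]
        resid = y.to_numpy() - x @ coef
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1 - (resid @ resid) / tss
        adj = 1 - (1 - r2) * (n - 1) / (n - x.shape[1])
        assert table.loc["M_base", "adj_r2"] == pytest.approx(adj, abs=1e-12)

    def test_nested_chain_monotone_on_signal(self, study, prep):
        ph2 = prep["phenotypes"][prep["phenotypes"]["timepoint"] == 2]
        from methlung.ewas import ModelSpec, build_design, outcome_vector
        dm = build_design(ph2, prep["cell_fractions"], ModelSpec())
        ph2 = ph2.loc[dm.index]
        cpg_set = mediation_cpg_set(study["effects"])
        idx = build_index(prep["residuals"][list(ph2.index)], cpg_set)
        smok = pd.DataFrame({
            "ex": (ph2["smoking_status"] == "ex").astype(float),
            "cur": (ph2["smoking_status"] == "current").astype(float),
            "py": ph2["pack_years"].astype(float)})
        table = variance_decomposition(outcome_vector(ph2, "fev1_fvc"), dm,
                                       idx.scores, smok)
        assert table.loc["M_base+index", "adj_r2"] \
            >= table.loc["M_base", "adj_r2"]
        assert table.loc["M_smok+index", "adj_r2"] \
            >= table.loc["M_smok", "adj_r2"]

    def test_sample_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        design = self._design(rng, 50)
        y = pd.Series(rng.normal(size=50), index=design.index)
        idx = pd.Series(rng.normal(size=10),
                        index=[f"other{j}" for j in range(10)])
        smok = pd.DataFrame({"z": rng.normal(size=50)}, index=design.index)
        with pytest.raises(ValueError, match="samples"):
            variance_decomposition(y, design, idx, smok)


class TestGroupDistribution:
    def test_independent_adjustment_leaves_medians(self):
        rng = np.random.default_rng(11)
        n = 600
        idx = pd.Series(rng.normal(size=n),
                        index=[f"s{j}" for j in range(n)])
        groups = pd.Series(rng.choice(["a", "b", "c"], n), index=idx.index)
        adjust = pd.DataFrame({"z": rng.normal(size=n)}, index=idx.index)
        out = adjusted_group_distribution(idx, groups, adjust)
        for g, sub in idx.groupby(groups):
            assert out.loc[g, "median"] == pytest.approx(sub.median(),
                                                         abs=0.15)
        assert out["n"].sum() == n

    def test_monotone_pack_year_bins_on_synthetic_cohort(self, study, prep):
        """Adjusted index medians rise across pack-year bins in current
        smokers (dose-response gradient)."""
        ph2 = prep["phenotypes"][prep["phenotypes"]["timepoint"] == 2]
        cur = ph2[ph2["smoking_status"] == "current"]
        cpg_set = mediation_cpg_set(study["effects"])
        idx = build_index(prep["residuals"][list(cur.index)], cpg_set)
        bins = pd.Series(pd.qcut(cur["pack_years"], 3, labels=False),
                         index=cur.index)
        adjust = cur[["age", "sex"]].astype(float)
        out = adjusted_group_distribution(idx.scores, bins, adjust)
        assert out["median"].is_monotonic_increasing

    def test_collinear_grouping_rejected(self):
        rng = np.random.default_rng(12)
        n = 60
        idx = pd.Series(rng.normal(size=n),
                        index=[f"s{j}" for j in range(n)])
        groups = pd.Series(np.where(np.arange(n) < 30, "a", "b"),
                           index=idx.index)
        adjust = pd.DataFrame(
            {"ind": (groups == "a").astype(float)}, index=idx.index)
        with pytest.raises(ValueError, match="collinear"):
            adjusted_group_distribution(idx, groups, adjust)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(13)
        idx = pd.Series(rng.normal(size=10),
                        index=[f"s{j}" for j in range(10)])
        groups = pd.Series("only", index=idx.index)
        adjust = pd.DataFrame({"z": rng.normal(size=10)}, index=idx.index)
        with pytest.raises(ValueError, match="grouping"):
            adjusted_group_distribution(idx, groups, adjust)
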