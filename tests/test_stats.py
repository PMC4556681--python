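"""Evaluation statistics: sd reduction, displacement, ANOVA, tests, t-fit."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from scipy.special import polygamma
from scipy.optimize import brentq

import lemnorm as ln
from lemnorm.errors import ParameterError
from lemnorm.stats import kuiper_p_asymptotic, moderated_t_prior

from helpers import (build_design, build_table, nested_ss_oracle,
                     signed_rank_exact_p)


def _matrices(seed=0, n_genes=3, n_samples=8):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    raw = pd.DataFrame(rng.uniform(18, 30, (n_genes, n_samples)),
                       index=genes, columns=samples)
    groups = ["control"] * (n_samples // 2) + ["treated"] * (n_samples // 2)
    design = build_design(samples, groups, "control")
    return raw, design


class TestSdReduction:
    def test_identity_gives_zero(self):
        raw, design = _matrices()
        res = ln.sd_reduction(raw, raw.copy(), design)
        assert np.allclose(res.per_cell["reduction_pct"], 0.0)

    def test_halved_deviations_give_fifty_percent(self):
        raw, design = _matrices(1)
        groups = raw.columns.map(design.table["group"])
        processed = raw.copy()
        for grp in ("control", "treated"):
            cols = raw.columns[groups == grp]
            mean = raw[cols].mean(axis=1)
            processed[cols] = mean.values[:, None] + \
                (raw[cols].values - mean.values[:, None]) / 2.0
        res = ln.sd_reduction(raw, processed, design)
        assert np.allclose(res.per_cell["reduction_pct"], 50.0)

    def test_matches_two_pass_sd_oracle(self):
        raw, design = _matrices(2)
        processed = raw * 0.9 + 1.3
        res = ln.sd_reduction(raw, processed, design)
        groups = raw.columns.map(design.table["group"])
        for _, row in res.per_cell.iterrows():
            cols = raw.columns[groups == row["group"]]
            x = raw.loc[row["gene"], cols].to_numpy()
            y = processed.loc[row["gene"], cols].to_numpy()
            sd = lambda v: np.sqrt(np.sum((v - v.mean()) ** 2) / (len(v) - 1))
            assert row["sd_raw"] == pytest.approx(sd(x))
            assert row["reduction_pct"] == pytest.approx(
                100 * (1 - sd(y) / sd(x)))


class TestMeanDisplacement:
    def test_balanced_constants_give_zero(self):
        raw, design = _matrices(3)
        processed = raw + 0.7        # same shift everywhere cancels
        rel, med = ln.mean_displacement(raw, processed, design)
        assert np.allclose(rel.values, 0.0, atol=1e-12)

    def test_constructed_group_shift_recovered(self):
        raw, design = _matrices(4)
        groups = raw.columns.map(design.table["group"])
        processed = raw.copy()
        cols = raw.columns[groups == "treated"]
        processed[cols] = processed[cols] - 0.28
        rel, med = ln.mean_displacement(raw, processed, design)
        assert np.allclose(rel["treated"].values, -0.28)
        assert med["treated"] == pytest.approx(-0.28)


class TestVarianceDecomposition:
    def _nested_records(self, seed=0, bio_sd=1.0, cdna_sd=0.0, pcr_sd=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("g1", "g2"):
            for b in range(3):
                bio = rng.normal(0, bio_sd)
                for c in range(2):
                    cdna = rng.normal(0, cdna_sd)
                    for r in range(1, 3):
                        rows.append({"gene": g, "sample": f"b{b}_c{c}",
                                     "array": "1", "pcr_rep": r, "assay_rep": 1,
                                     "ct": 25 + bio + cdna
                                     + rng.normal(0, pcr_sd)})
        t = ln.CtTable.from_records(pd.DataFrame(rows))
        samples = t.samples
        design = build_design(samples, ["all"] * len(samples), "all",
                              bio_reps=[s.split("_")[0] for s in samples],
                              cdna_batches=samples)
        return t, design

    def test_single_source_gets_full_proportion(self):
        t, design = self._nested_records(bio_sd=1.0)
        vd = ln.variance_decomposition(t, design, ["bio_rep", "cdna_batch"])
        assert np.allclose(vd.proportions["bio_rep"], 1.0)
        assert np.allclose(vd.proportions[["cdna_batch", "residual"]], 0.0,
                           atol=1e-9)

    def test_matches_nested_anova_oracle(self):
        t, design = self._nested_records(seed=5, bio_sd=0.8, cdna_sd=0.5,
                                         pcr_sd=0.3)
        vd = ln.variance_decomposition(t, design, ["bio_rep", "cdna_batch"])
        df = t.records
        for g in ("g1", "g2"):
            sub = df[df["gene"] == g]
            bio = sub["sample"].map(design.table["bio_rep"]).to_numpy()
            cdna = sub["sample"].to_numpy()
            ss = nested_ss_oracle(sub["ct"].to_numpy(), [bio, cdna])
            assert np.allclose(vd.ss.loc[g].values, ss, atol=1e-9)

    def test_proportions_sum_to_one_and_order_invariant(self):
        t, design = self._nested_records(seed=6, bio_sd=0.5, cdna_sd=0.5,
                                         pcr_sd=0.5)
        vd = ln.variance_decomposition(t, design, ["bio_rep", "cdna_batch"])
        assert np.allclose(vd.proportions.sum(axis=1), 1.0, atol=1e-9)
        shuffled = ln.CtTable.from_records(
            t.records.sample(frac=1, random_state=0))
        vd2 = ln.variance_decomposition(shuffled, design,
                                        ["bio_rep", "cdna_batch"])
        assert np.allclose(vd.proportions.loc[vd2.proportions.index].values,
                           vd2.proportions.values)

    def test_single_level_factor_contributes_zero(self):
        t, design = self._nested_records(seed=7, bio_sd=0.5, pcr_sd=0.2)
        vd = ln.variance_decomposition(t, design, ["group", "bio_rep"])
        assert np.allclose(vd.proportions["group"], 0.0, atol=1e-12)


class TestSdVsMeanRegression:
    def _table(self, sd_fn, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(10)]
        means = np.linspace(20, 32, 10)
        rows = []
        for g, mu in zip(genes, means):
            devs = np.array([-1.0, 0.0, 1.0]) * sd_fn(mu)
            for r, dv in enumerate(devs, 1):
                rows.append({"gene": g, "sample": f"s{r}", "array": "1",
                             "pcr_rep": 1, "assay_rep": 1, "ct": mu + dv})
        return ln.CtTable.from_records(pd.DataFrame(rows))

    def test_constant_sd_zero_slope(self):
        t = self._table(lambda mu: 0.3)
        res = ln.sd_vs_mean_regression(t)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_sd_recovered_exactly(self):
        a, b = 0.05, 0.02
        t = self._table(lambda mu: a + b * mu)
        res = ln.sd_vs_mean_regression(t)
        assert res.slope == pytest.approx(b, rel=1e-9)
        assert res.intercept == pytest.approx(a, rel=1e-6)
        assert res.positive_slope

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        t = self._table(lambda mu: 0.1 + 0.01 * mu + 0.05 * rng.random())
        res = ln.sd_vs_mean_regression(t)
        x = res.points["mean"].to_numpy()
        y = res.points["std"].to_numpy()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(y.mean() - slope * x.mean())


class TestDiffExpression:
    def test_identical_groups_give_t_zero_p_one(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["g"],
                         columns=[f"s{i}" for i in range(6)])
        design = build_design(m.columns, ["control"] * 3 + ["treated"] * 3,
                              "control")
        res = ln.diff_expression(m, design, method="welch", correction="none")
        assert res["statistic"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.normal(25, 1, (5, 12)),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"s{i}" for i in range(12)])
        design = build_design(m.columns, ["control"] * 6 + ["treated"] * 6,
                              "control")
        res = ln.diff_expression(m, design, correction="none").set_index("gene")
        for g in m.index:
            a = m.loc[g].iloc[6:]
            b = m.loc[g].iloc[:6]
            t, p = st.ttest_ind(a, b, equal_var=False)
            assert res.loc[g, "statistic"] == pytest.approx(t)
            assert res.loc[g, "p"] == pytest.approx(p)

    def test_moderated_matches_shrinkage_formula_oracle(self):
        rng = np.random.default_rng(13)
        gene_sd = np.exp(rng.normal(0, 0.7, 40))      # heterogeneous variances
        m = pd.DataFrame(rng.normal(0, 1, (40, 10)) * gene_sd[:, None],
                         index=[f"g{i}" for i in range(40)],
                         columns=[f"s{i}" for i in range(10)])
        design = build_design(m.columns, ["control"] * 5 + ["treated"] * 5,
                              "control")
        res = ln.diff_expression(m, design, method="moderated",
                                 correction="none", robust=False).set_index("gene")
        A, B = m.iloc[:, 5:].values, m.iloc[:, :5].values
        sp2 = (A.var(axis=1, ddof=1) * 4 + B.var(axis=1, ddof=1) * 4) / 8
        # independent prior estimate: solve the trigamma equation by brentq
        z = np.log(sp2)
        e = z - polygamma(0, 4.0) + np.log(4.0)
        target = e.var(ddof=1) - polygamma(1, 4.0)
        assert target > 0
        half_d0 = brentq(lambda x: polygamma(1, x) - target, 1e-3, 1e6)
        d0 = 2 * half_d0
        s02 = np.exp(e.mean() + polygamma(0, half_d0) - np.log(half_d0))
        s2post = (d0 * s02 + 8 * sp2) / (d0 + 8)
        tstat = (A.mean(axis=1) - B.mean(axis=1)) / np.sqrt(s2post * (2 / 5))
        for i, g in enumerate(m.index):
            assert res.loc[g, "statistic"] == pytest.approx(tstat[i], rel=1e-6)
            assert res.loc[g, "df"] == pytest.approx(d0 + 8, rel=1e-6)

    def test_moderated_limits(self):
        # prior df -> 0 recovers the ordinary pooled t; -> inf the fixed-s0 z
        s2 = np.array([0.5, 1.0, 2.0])
        dg = np.array([8.0, 8.0, 8.0])
        d0, s02 = moderated_t_prior(np.full(50, 1.0), 8.0, robust=False)
        assert np.isinf(d0)          # identical variances -> infinite prior df
        post_small = (1e-12 * s02 + dg * s2) / (1e-12 + dg)
        assert np.allclose(post_small, s2)

    def test_bonferroni_caps_at_one(self):
        raw, design = _matrices(9, n_genes=4)
        res = ln.diff_expression(raw, design, correction="bonferroni")
        assert (res["p_adj"] <= 1.0).all()
        res_n = ln.diff_expression(raw, design, correction="bonferroni",
                                   bonferroni_n=48)
        ok = res["p"].notna()
        assert np.allclose(res_n.loc[ok, "p_adj"],
                           np.minimum(res.loc[ok, "p"] * 48, 1.0))


class TestPairedSdTests:
    def test_equal_vectors_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = ln.paired_sd_tests(a, a.copy(), method="sign")
        assert res.p == 1.0
        assert res.n_used == 0

    def test_sign_test_closed_form(self):
        a = np.arange(6) + 1.0
        b = a - 0.5          # all positive differences
        res = ln.paired_sd_tests(a, b, method="sign")
        assert res.p == pytest.approx(2 * 0.5 ** 6)

    def test_signed_rank_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        a = rng.normal(1.0, 0.3, 10)
        b = a - rng.normal(0.15, 0.2, 10)
        res = ln.paired_sd_tests(a, b, method="wilcoxon_signed_rank")
        assert res.p == pytest.approx(signed_rank_exact_p(a - b))

    def test_short_vectors_rejected(self):
        with pytest.raises(ParameterError):
            ln.paired_sd_tests([1, 2], [2, 1])


class TestResidualTFit:
    def test_t5_parameters_recovered(self):
        rng = np.random.default_rng(19)
        x = st.t.rvs(5, size=10_000, random_state=rng)
        fit = ln.fit_residual_t(x, p_method="asymptotic")
        assert 3.5 <= fit.df <= 7.0
        assert fit.location == pytest.approx(0.0, abs=0.05)
        assert fit.scale == pytest.approx(1.0, abs=0.05)

    def test_normal_data_fits_large_df(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=5_000)
        fit = ln.fit_residual_t(x, p_method="asymptotic")
        assert fit.df > 30
        assert fit.ks_p > 0.05

    def test_kuiper_statistic_hand_oracle(self):
        # five points against the uniform cdf on [0, 1]
        x = np.array([0.1, 0.2, 0.5, 0.7, 0.9])
        u = np.sort(x)
        i = np.arange(1, 6)
        d_plus = np.max(i / 5 - u)
        d_minus = np.max(u - (i - 1) / 5)
        got = ln.kuiper_statistic(x, lambda v: v)
        assert got == pytest.approx(d_plus + d_minus)

    def test_kuiper_cyclic_invariance_ks_not(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(size=200)
        shift = 0.37
        y = (x + shift) % 1.0
        ident = lambda v: np.clip(v, 0, 1)
        v_x = ln.kuiper_statistic(x, ident)
        v_y = ln.kuiper_statistic(y, ident)
        ks_x = st.kstest(x, ident).statistic
        ks_y = st.kstest(y, ident).statistic
        assert v_x == pytest.approx(v_y, abs=0.02)
        # a cyclic shift of a non-uniform circular sample moves KS much more
        x2 = np.concatenate([rng.uniform(0, 0.3, 150), rng.uniform(0.3, 1, 50)])
        y2 = (x2 + shift) % 1.0
        assert abs(st.kstest(x2, ident).statistic
                   - st.kstest(y2, ident).statistic) > \
            abs(ln.kuiper_statistic(x2, ident) - ln.kuiper_statistic(y2, ident))

    def test_bootstrap_p_in_range(self):
        rng = np.random.default_rng(29)
        x = st.t.rvs(5, size=300, random_state=rng)
        fit = ln.fit_residual_t(x, n_boot=49, p_method="bootstrap", seed=1)
        assert 0.0 < fit.ks_p <= 1.0
        assert 0.0 < fit.kuiper_p <= 1.0

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ParameterError):
            ln.fit_residual_t(np.ones(10))
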