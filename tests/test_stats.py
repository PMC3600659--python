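import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from revlearn import stats


def _long(Y, groups=None, factor="w"):
    """Long-format frame from a subjects x levels matrix."""
    N, k = Y.shape
    rows = []
    for i in range(N):
        for j in range(k):
            rows.append({"subject": f"s{i:03d}", factor: j + 1,
                         "y": Y[i, j],
                         "group": "g0" if groups is None else groups[i]})
    return pd.DataFrame(rows)


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        S = 0.3 * np.ones((4, 4)) + 0.7 * np.eye(4)
        assert stats.gg_epsilon(S) == pytest.approx(1.0)

    def test_lower_bound_k4(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            A = rng.normal(size=(4, 6))
            S = A @ A.T
            eps = stats.gg_epsilon(S)
            assert 1.0 / 3 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_formula_oracle(self):
        # independent textbook computation: epsilon from the elements of
        # the double-centered matrix, (sum of diag)^2 / ((k-1) * sum sq)
        S = np.array([[1.0, 0.5, 0.25],
                      [0.5, 1.0, 0.5],
                      [0.25, 0.5, 1.0]])
        k = 3
        row_means = S.mean(axis=1)
        grand = S.mean()
        Sc = S - row_means[:, None] - row_means[None, :] + grand
        eps_oracle = np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc * Sc))
        assert stats.gg_epsilon(S) == pytest.approx(eps_oracle, abs=1e-10)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            stats.gg_epsilon(np.array([[1.0, 0.9], [0.1, 1.0]]))


class TestMixedAnova:
    def test_between_f_matches_one_way_oracle(self):
        # responses constant within participant => the between test
        # reduces exactly to a one-way ANOVA on subject values
        rng = np.random.default_rng(1)
        groups = ["a"] * 8 + ["b"] * 7 + ["c"] * 9
        shift = {"a": 0.0, "b": 1.0, "c": 2.0}
        u = np.array([shift[g] for g in groups]) + rng.normal(0, 1, 24)
        Y = np.tile(u[:, None], (1, 4))
        tab = stats.mixed_anova(_long(Y, groups), "y", ["w"], "subject",
                                between="group")
        # hand-computed one-way SS oracle
        grand = u.mean()
        ss_b = sum(len([x for x, g in zip(u, groups) if g == lab])
                   * (np.mean([x for x, g in zip(u, groups) if g == lab])
                      - grand) ** 2 for lab in "abc")
        ss_w = sum((x - np.mean([xx for xx, gg in zip(u, groups)
                                 if gg == g])) ** 2
                   for x, g in zip(u, groups))
        f_oracle = (ss_b / 2) / (ss_w / 21)
        row = tab[tab["source"] == "group"].iloc[0]
        assert row["F"] == pytest.approx(f_oracle, rel=1e-10)
        assert row["df1"] == 2 and row["df2"] == 21
        p_oracle = sps.f.sf(f_oracle, 2, 21)
        assert row["p"] == pytest.approx(p_oracle, rel=1e-10)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(12, 4))
        groups = ["a"] * 6 + ["b"] * 6
        t1 = stats.mixed_anova(_long(Y, groups), "y", ["w"], "subject",
                               between="group")
        t2 = stats.mixed_anova(_long(Y + 100.0, groups), "y", ["w"],
                               "subject", between="group")
        assert np.allclose(t1["F"], t2["F"])

    def test_group_permutation_null_p_uniform(self):
        # permuting group labels on null data must give uniform p
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(18, 3))
        base_groups = np.array(["a"] * 9 + ["b"] * 9)
        pvals = []
        for _ in range(300):
            g = rng.permutation(base_groups)
            tab = stats.mixed_anova(_long(Y, g), "y", ["w"], "subject",
                                    between="group")
            pvals.append(float(tab.loc[tab["source"] == "group", "p"].iloc[0]))
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_two_within_factors_decomposition(self):
        rng = np.random.default_rng(4)
        # 2x3 within design, 10 subjects, additive effects
        N = 10
        a_eff = np.array([0.0, 2.0])
        b_eff = np.array([0.0, 1.0, -1.0])
        rows = []
        for i in range(N):
            base = rng.normal()
            for ai in range(2):
                for bi in range(3):
                    rows.append({"subject": f"s{i}", "A": ai, "B": bi,
                                 "y": base + a_eff[ai] + b_eff[bi]
                                 + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        tab = stats.mixed_anova(df, "y", ["A", "B"], "subject")
        srcs = set(tab["source"])
        assert {"A", "B", "A * B"} <= srcs
        assert float(tab.loc[tab["source"] == "A", "p"].iloc[0]) < 0.01
        assert float(tab.loc[tab["source"] == "B", "p"].iloc[0]) < 0.01
        assert float(tab.loc[tab["source"] == "A * B", "p"].iloc[0]) > 0.01

    def test_gg_correction_never_lowers_p_in_rejection_region(self):
        # the GG df reduction raises the critical value, so in the
        # decision-relevant tail (small p) the corrected p can only be
        # larger; near the distribution center the ordering can invert,
        # which is why the check is restricted to p_unc < 0.2
        checked = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            Y = rng.normal(size=(9, 4))
            Y[:, 0] += rng.normal(size=9) * 2       # break sphericity
            Y += rng.normal(size=4) * 1.2           # within effect
            tab = stats.mixed_anova(_long(Y), "y", ["w"], "subject")
            row = tab[tab["source"] == "w"].iloc[0]
            if row["p_unc"] < 0.2:
                checked += 1
                assert row["p_gg"] >= row["p_unc"] - 1e-12
        assert checked >= 10

    def test_unbalanced_cells_rejected(self):
        df = _long(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="cells"):
            stats.mixed_anova(df.iloc[:-1], "y", ["w"], "subject")


class TestAncovaRM:
    def _design(self, seed, n=21, slope=0.0, noise=1.0):
        rng = np.random.default_rng(seed)
        cov = rng.normal(size=n)
        Y = (slope * cov)[:, None] + rng.normal(0, noise, size=(n, 4))
        return _long(Y), cov

    def test_covariate_power(self):
        hits = 0
        for seed in range(60):
            df, cov = self._design(seed, slope=1.2, noise=0.8)
            tab = stats.ancova_rm(df, "y", ["w"], "subject", {"c": cov})
            hits += float(tab.loc[tab["source"] == "c", "p"].iloc[0]) < 0.05
        assert hits / 60 >= 0.95

    def test_covariate_null_uniform(self):
        pvals = []
        for seed in range(300):
            df, cov = self._design(seed + 1000, slope=0.0)
            tab = stats.ancova_rm(df, "y", ["w"], "subject", {"c": cov})
            pvals.append(float(tab.loc[tab["source"] == "c", "p"].iloc[0]))
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_covariate_main_effect_matches_regression_oracle(self):
        # responses constant across within levels: the covariate test is
        # exactly the slope t-test of a simple regression on subject means
        rng = np.random.default_rng(6)
        n = 15
        cov = rng.normal(size=n)
        u = 0.7 * cov + rng.normal(0, 1, n)
        Y = np.tile(u[:, None], (1, 3))
        tab = stats.ancova_rm(_long(Y), "y", ["w"], "subject", {"c": cov})
        res = sps.linregress(cov, u)
        row = tab[tab["source"] == "c"].iloc[0]
        assert row["F"] == pytest.approx(res.rvalue**2 / (1 - res.rvalue**2)
                                         * (n - 2), rel=1e-10)
        assert row["p"] == pytest.approx(res.pvalue, rel=1e-9)

    def test_duplicate_covariate_collinearity_error(self):
        df, cov = self._design(7)
        with pytest.raises(ValueError, match="collinear"):
            stats.ancova_rm(df, "y", ["w"], "subject",
                            {"c1": cov, "c2": cov})

    def test_constant_covariate_rejected(self):
        df, _ = self._design(8)
        with pytest.raises(ValueError, match="constant"):
            stats.ancova_rm(df, "y", ["w"], "subject", {"c": np.ones(21)})

    def test_interaction_term_reported(self):
        df, cov = self._design(9)
        tab = stats.ancova_rm(df, "y", ["w"], "subject", {"c": cov})
        assert "w * c" in set(tab["source"])


class TestPosthoc:
    def _df(self, means, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for gi, mu in enumerate(means):
            for i in range(n):
                rows.append({"subject": f"g{gi}s{i}", "group": f"g{gi}",
                             "y": mu + rng.normal()})
        return pd.DataFrame(rows)

    def test_identical_groups_large_p(self):
        df = self._df([0.0, 0.0], n=30, seed=1)
        out = stats.posthoc(df, "y", "group", "subject", method="lsd")
        assert out["p"].iloc[0] > 0.05

    def test_three_groups_bonferroni_triples_p(self):
        df = self._df([0.0, 0.3, 0.6], seed=2)
        lsd = stats.posthoc(df, "y", "group", "subject", method="lsd")
        bon = stats.posthoc(df, "y", "group", "subject", method="bonferroni")
        assert len(lsd) == 3
        for i in range(3):
            assert bon["p"].iloc[i] == pytest.approx(
                min(1.0, 3 * lsd["p"].iloc[i]))

    def test_pooled_t_oracle(self):
        df = self._df([0.0, 1.0], n=12, seed=3)
        out = stats.posthoc(df, "y", "group", "subject", method="lsd")
        xa = df[df["group"] == "g0"]["y"].to_numpy()
        xb = df[df["group"] == "g1"]["y"].to_numpy()
        t_ref, p_ref = sps.ttest_ind(xa, xb)
        assert out["t"].iloc[0] == pytest.approx(t_ref, rel=1e-10)
        assert out["p"].iloc[0] == pytest.approx(p_ref, rel=1e-10)
        assert out["df"].iloc[0] == 22

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            stats.posthoc(self._df([0, 1]), "y", "group", "subject",
                          method="tukey")
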