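"""Statistical battery: oracle equivalences, cross-checks against
independent implementations, letter-display consistency, and exact tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ommatidics import stats as st
from ommatidics import synth
from ommatidics.model import (
    ContingencyTable,
    EstimabilityError,
    ResourceError,
    ValidationError,
)


def _toy_ancova_frame(rng, k=3, n_per=10, offsets=(0.0, 0.8, 0.3), slope=0.5, sd=0.4):
    groups = np.repeat([f"g{i}" for i in range(k)], n_per)
    x = rng.normal(2.0, 0.5, k * n_per)
    y = slope * x + np.repeat(offsets[:k], n_per) + rng.normal(0, sd, k * n_per)
    return pd.DataFrame({"g": groups, "x": x, "y": y})


class TestMancovaCore:
    def test_univariate_collapse_wilks_equals_ancova_F(self, rng):
        df = _toy_ancova_frame(rng)
        fit = st.fit_mancova(df, ["y"], "g", "x")
        uni = st.ancova(df, "y", "g", "x")
        assert fit.wilks.F == pytest.approx(uni["group"].F, abs=1e-8)
        assert fit.pillai.F == pytest.approx(uni["group"].F, abs=1e-8)
        assert fit.wilks.p == pytest.approx(uni["group"].p, abs=1e-10)

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        df = _toy_ancova_frame(rng)
        df["y2"] = 1.0 - 0.2 * df.x + (df.g == "g1") * 0.2 + rng.normal(0, 0.3, len(df))
        fit = st.fit_mancova(df, ["y", "y2"], "g", "x")
        ref = MANOVA.from_formula("y + y2 ~ C(g) + x", data=df).mv_test()
        tab = ref.results["C(g)"]["stat"]
        assert fit.wilks.statistic == pytest.approx(
            tab.loc["Wilks' lambda", "Value"], abs=1e-10
        )
        assert fit.wilks.F == pytest.approx(tab.loc["Wilks' lambda", "F Value"], abs=1e-8)
        assert fit.pillai.statistic == pytest.approx(
            tab.loc["Pillai's trace", "Value"], abs=1e-10
        )
        cov = ref.results["x"]["stat"]
        assert fit.covariate_wilks.statistic == pytest.approx(
            cov.loc["Wilks' lambda", "Value"], abs=1e-10
        )

    def test_emm_closed_form_common_slope(self, rng):
        # EMM_g = ybar_g + b (xbar - xbar_g) for the common-slope model
        df = _toy_ancova_frame(rng)
        fit = st.fit_mancova(df, ["y"], "g", "x")
        xbar = df.x.mean()
        # common slope from the fitted model via contrast-free identity:
        # pooled within-group regression
        slope = fit._fit.B[fit._cov_col, 0]
        for g, sub in df.groupby("g"):
            expect = sub.y.mean() + slope * (xbar - sub.x.mean())
            got = fit.emm_table.query("group == @g")["emm"].iloc[0]
            assert got == pytest.approx(expect, abs=1e-10)

    def test_centered_covariate_emms_equal_raw_means(self, rng):
        # every group sees the same zero-mean covariate values, so the EMM
        # at 0 is exactly the raw group mean
        df = _toy_ancova_frame(rng)
        x0 = df.loc[df.g == "g0", "x"].to_numpy()
        x0 = x0 - x0.mean()
        for g in ("g0", "g1", "g2"):
            df.loc[df.g == g, "x"] = x0
        df["y"] = 0.5 * df.x + (df.g == "g1") * 1.0 + np.asarray(
            rng.normal(0, 0.3, len(df))
        )
        fit = st.fit_mancova(df, ["y"], "g", "x", emm_at=0.0)
        for g, sub in df.groupby("g"):
            got = fit.emm_table.query("group == @g")["emm"].iloc[0]
            assert got == pytest.approx(sub.y.mean(), abs=1e-10)

    def test_emm_reevaluation_matches_refit(self, rng):
        df = _toy_ancova_frame(rng)
        fit = st.fit_mancova(df, ["y"], "g", "x")
        moved = st.estimated_marginal_means(fit, at_covariate=1.9)
        refit = st.fit_mancova(df, ["y"], "g", "x", emm_at=1.9)
        assert np.allclose(moved["emm"], refit.emm_table["emm"], atol=1e-12)
        assert np.allclose(moved["se"], refit.emm_table["se"], atol=1e-12)

    def test_known_offsets_recovered_within_2se(self, rng):
        spec = synth.MorphoSimSpec(
            species=[
                synth.SpeciesLine("a", facet_diameter_D=(12.0, 4.0)),
                synth.SpeciesLine("b", facet_diameter_D=(18.0, 4.0)),
            ],
            n_workers=12,
            seed=77,
        )
        df = synth.synth_morphometry(spec)
        fit = st.fit_mancova(
            df, ["facet_diameter_D"], "species_id", "mesosoma_length"
        )
        diff, se = st.emm_contrast(fit, "b", "a", "facet_diameter_D")
        assert abs(diff - 6.0) <= 2 * se

    def test_small_sample_precondition(self, rng):
        df = _toy_ancova_frame(rng, k=3, n_per=1)
        with pytest.raises(ValidationError):
            st.fit_mancova(df, ["y"], "g", "x")

    def test_group_type1_error_nominal(self, rng):
        # null simulation: no group effect; rejection rate ~ alpha
        reject = 0
        reps = 500
        for r in range(reps):
            df = _toy_ancova_frame(rng, k=2, n_per=10, offsets=(0.0, 0.0, 0.0))
            fit = st.fit_mancova(df, ["y"], "g", "x")
            reject += fit.wilks.p < 0.05
        # binomial 99% bounds around 0.05
        lo, hi = sps.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= reject <= hi


class TestAncova:
    def test_orthogonal_covariate_leaves_group_ss_and_emms_unchanged(self, rng):
        # exact orthogonality identity: when each group sees identical
        # covariate values, the type-III group SS equals the one-way
        # between-group SS and the adjusted group differences equal the raw
        # mean differences (the covariate changes only the error term)
        df = _toy_ancova_frame(rng, k=2, offsets=(0.0, 1.0))
        x0 = df.loc[df.g == "g0", "x"].to_numpy()
        df.loc[df.g == "g1", "x"] = x0
        a = st.ancova(df, "y", "g", "x")
        f1 = st.one_way_anova(df, "y", "g")
        df_b, df_w = f1["df"]
        ss_between = f1["F"] * df_b * f1["mse"]
        assert a["group"].ss == pytest.approx(ss_between, rel=1e-8)
        d0 = df.query("g == 'g1'").y.mean() - df.query("g == 'g0'").y.mean()
        emm = a["emm"]
        diff = (
            emm.query("group == 'g1'")["emm"].iloc[0]
            - emm.query("group == 'g0'")["emm"].iloc[0]
        )
        assert diff == pytest.approx(d0, abs=1e-10)

    def test_slopes_interaction_null_uniform(self, rng):
        # equal-slope data: interaction p approximately uniform
        ps = []
        for _ in range(200):
            df = _toy_ancova_frame(rng, k=2, n_per=10, offsets=(0.0, 0.0))
            ps.append(st.ancova(df, "y", "g", "x", test_slopes=True)["interaction"].p)
        ks = sps.kstest(ps, "uniform").pvalue
        assert ks > 0.001

    def test_perfect_fit_flagged(self):
        df = pd.DataFrame(
            {"g": ["a"] * 4 + ["b"] * 4, "x": [1, 2, 3, 4] * 2}
        )
        df["y"] = 2.0 * df.x + (df.g == "b") * 3.0  # zero residual
        a = st.ancova(df, "y", "g", "x")
        assert a["group"].degenerate
        assert a["group"].p == 0.0


class TestTwoWayAncova:
    @staticmethod
    def _frame(rng, ab_effect=0.0, n_per=8):
        rows = []
        for a in ("g1", "g2"):
            for b in ("noct", "diur"):
                x = rng.normal(1.8, 0.3, n_per)
                sign = 1.0 if (a == "g1") == (b == "noct") else -1.0
                y = 0.4 * x + sign * ab_effect + np.asarray(rng.normal(0, 0.5, n_per))
                for xi, yi in zip(x, y):
                    rows.append({"A": a, "B": b, "x": xi, "y": yi})
        return pd.DataFrame(rows)

    def test_matches_statsmodels_type3(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = self._frame(rng, ab_effect=0.4)
        res = st.two_way_ancova(df, "y", "A", "B", "x")
        ols = smf.ols(
            "y ~ C(A, Sum) * C(B, Sum) + x", data=df
        ).fit()
        tab = sm.stats.anova_lm(ols, typ=3)
        assert res["A"].F == pytest.approx(tab.loc["C(A, Sum)", "F"], rel=1e-8)
        assert res["B"].F == pytest.approx(tab.loc["C(B, Sum)", "F"], rel=1e-8)
        assert res["A:B"].F == pytest.approx(
            tab.loc["C(A, Sum):C(B, Sum)", "F"], rel=1e-8
        )
        assert res["x"].F == pytest.approx(tab.loc["x", "F"], rel=1e-8)

    def test_single_level_factor_collapses_to_ancova(self, rng):
        df = self._frame(rng)
        df["B"] = "noct"
        res = st.two_way_ancova(df, "y", "A", "B", "x")
        assert res["collapsed_to"] == "A"
        assert "group" in res

    def test_empty_cell_estimability_error(self, rng):
        df = self._frame(rng)
        df = df[~((df.A == "g1") & (df.B == "diur"))]
        with pytest.raises(EstimabilityError):
            st.two_way_ancova(df, "y", "A", "B", "x")

    def test_opposite_sign_interaction_detected(self, rng):
        df = self._frame(rng, ab_effect=0.8, n_per=10)
        res = st.two_way_ancova(df, "y", "A", "B", "x")
        assert res["A:B"].p < 0.05


class TestLetterDisplays:
    def test_clear_separation(self):
        res = st.lsd_letters([10.0, 10.0, 2.0], [0.01, 0.01, 0.01], df=10)
        assert res.letters == {"g0": "a", "g1": "a", "g2": "b"}

    def test_all_equal_share_one_letter(self):
        res = st.lsd_letters([5.0, 5.0, 5.0], [1.0, 1.0, 1.0], df=10)
        assert set(res.letters.values()) == {"a"}

    def test_chained_overlap_matches_clique_oracle(self, rng):
        import networkx as nx

        for _ in range(100):
            k = int(rng.integers(3, 6))
            means = rng.normal(0, 1, k)
            pm = np.ones((k, k))
            for i, j in itertools.combinations(range(k), 2):
                pm[i, j] = pm[j, i] = rng.uniform(0, 0.15)
            groups = [f"g{i}" for i in range(k)]
            letters = st.letters_from_pmatrix(groups, means, pm, 0.05)
            # oracle: maximal cliques of the non-significance graph
            G = nx.Graph()
            G.add_nodes_from(range(k))
            for i, j in itertools.combinations(range(k), 2):
                if pm[i, j] >= 0.05:
                    G.add_edge(i, j)
            cliques = {frozenset(c) for c in nx.find_cliques(G)}
            cols = {}
            for gi, s in letters.items():
                for ch in s:
                    cols.setdefault(ch, set()).add(groups.index(gi))
            assert {frozenset(c) for c in cols.values()} == cliques

    def test_letter_order_follows_descending_means(self):
        res = st.lsd_letters([2.0, 10.0], [0.01, 0.01], df=20)
        assert res.letters == {"g0": "b", "g1": "a"}


class TestFisherExact:
    @staticmethod
    def _brute_force(table):
        """Independent oracle: enumerate via itertools over the free cells."""
        table = np.asarray(table, dtype=int)
        rows, cols = table.sum(1), table.sum(0)
        N = table.sum()
        lg = math.lgamma
        const = (
            sum(lg(r + 1) for r in rows) + sum(lg(c + 1) for c in cols) - lg(N + 1)
        )

        def prob(t):
            return math.exp(const - sum(lg(x + 1) for x in np.ravel(t)))

        r, c = table.shape
        free = [range(min(rows[i], cols[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
        p_obs = prob(table)
        total = 0.0
        for combo in itertools.product(*free):
            t = np.zeros((r, c), dtype=int)
            t[: r - 1, : c - 1] = np.asarray(combo).reshape(r - 1, c - 1)
            t[: r - 1, c - 1] = rows[: r - 1] - t[: r - 1, : c - 1].sum(1)
            t[r - 1, :] = cols - t[: r - 1, :].sum(0)
            if (t >= 0).all():
                p = prob(t)
                if p <= p_obs * (1 + 1e-7):
                    total += p
        return min(total, 1.0)

    def test_focal_table_below_1e4(self):
        p = st.fisher_exact_rxc([[9, 1, 0], [0, 13, 3]])
        assert p < 1e-4
        assert p == pytest.approx(self._brute_force([[9, 1, 0], [0, 13, 3]]), rel=1e-10)

    def test_two_by_two_identity_table(self):
        assert st.fisher_exact_rxc([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_zero_row_degenerate(self):
        assert st.fisher_exact_rxc([[0, 0], [3, 4]]) == pytest.approx(1.0)

    def test_matches_scipy_on_2x2(self, rng):
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0:
                continue
            assert st.fisher_exact_rxc(t) == pytest.approx(
                sps.fisher_exact(t)[1], abs=1e-10
            )

    def test_matches_brute_force_on_small_tables(self, rng):
        for _ in range(30):
            r, c = rng.integers(2, 4, size=2)
            t = rng.integers(0, 5, size=(r, c))
            if t.sum() == 0 or t.sum() > 12:
                continue
            assert st.fisher_exact_rxc(t) == pytest.approx(
                self._brute_force(t), rel=1e-10
            )

    def test_contingency_table_input(self):
        tab = ContingencyTable(["p", "d"], ["n", "v", "d"], np.array([[9, 1, 0], [0, 13, 3]]))
        assert st.fisher_exact_rxc(tab) < 1e-4

    def test_guard_raises_resource_error(self):
        big = np.full((4, 4), 40, dtype=int)
        with pytest.raises(ResourceError):
            st.fisher_exact_rxc(big, guard=1000)


class TestBoxM:
    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(1)
        block = rng.normal(0, 1, (15, 2))
        df = pd.DataFrame(
            np.vstack([block, block]), columns=["y1", "y2"]
        )
        df["g"] = ["a"] * 15 + ["b"] * 15
        res = st.box_m(df, ["y1", "y2"], "g")
        assert res["M"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        df = pd.DataFrame(
            {
                "g": np.repeat(["a", "b", "c"], 20),
                "y1": rng.normal(0, 1, 60),
                "y2": rng.normal(0, 1, 60),
            }
        )
        mine = st.box_m(df, ["y1", "y2"], "g")
        ref = pg.box_m(df, dvs=["y1", "y2"], group="g")
        assert mine["chi2"] == pytest.approx(float(ref["Chi2"].iloc[0]), rel=1e-8)
        assert mine["p"] == pytest.approx(float(ref["pval"].iloc[0]), abs=1e-8)

    def test_power_against_10x_variance(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "g": np.repeat(["a", "b"], 20),
                    "y1": np.concatenate(
                        [rng.normal(0, 1, 20), rng.normal(0, math.sqrt(10), 20)]
                    ),
                    "y2": np.concatenate(
                        [rng.normal(0, 1, 20), rng.normal(0, math.sqrt(10), 20)]
                    ),
                }
            )
            hits += st.box_m(df, ["y1", "y2"], "g")["p"] < 0.001
        assert hits / reps > 0.9

    def test_group_too_small_named(self, rng):
        df = pd.DataFrame(
            {"g": ["a", "a", "a", "b", "b"], "y1": rng.normal(size=5), "y2": rng.normal(size=5)}
        )
        with pytest.raises(ValidationError, match="'b'"):
            st.box_m(df, ["y1", "y2"], "g")


class TestLevene:
    def test_identical_groups_F_zero(self):
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "y": [1.0, 2, 3, 4] * 2})
        res = st.levene(df, "y", "g")
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy(self, rng):
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 15), "y": rng.normal(0, 1, 45)}
        )
        res = st.levene(df, "y", "g")
        groups = [sub.y.to_numpy() for _, sub in df.groupby("g")]
        F, p = sps.levene(*groups, center="mean")
        assert res.F == pytest.approx(F) and res.p == pytest.approx(p)

    def test_power_variance_ratio_16(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "g": np.repeat(["a", "b"], 30),
                    "y": np.concatenate(
                        [rng.normal(0, 1, 30), rng.normal(0, 4, 30)]
                    ),
                }
            )
            hits += st.levene(df, "y", "g").p < 0.05
        assert hits / reps > 0.9


class TestRepeatedMeasures:
    def test_mauchly_df_for_five_levels(self):
        dat = synth.synth_regional_D(1.0, [0, 0, 0.5, 0, 2.0], 0.5, 14, seed=3)
        res = st.rm_anova(dat)
        assert res.df == 9
        assert res.n_levels == 5
        assert res.within_df == (4, 52)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        dat = synth.synth_regional_D(1.0, [0, 0.3, 0.5, 0, 1.0], 0.5, 14, seed=5)
        res = st.rm_anova(dat)
        long = dat.reset_index().melt(id_vars="index")
        ref = pg.rm_anova(
            data=long, dv="value", subject="index", within="variable", correction=True
        )
        assert res.within_F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.mauchly_W == pytest.approx(float(ref["W_spher"].iloc[0]), rel=1e-8)

    def test_compound_symmetric_null_uniform(self, rng):
        ps_w, ps_m = [], []
        for r in range(200):
            dat = synth.synth_regional_D(
                1.0, [0, 0, 0, 0, 0], 0.5, 12, seed=int(rng.integers(2**31))
            )
            res = st.rm_anova(dat)
            ps_w.append(res.within_p)
            ps_m.append(res.p)
        assert sps.kstest(ps_w, "uniform").pvalue > 0.001
        # under compound symmetry sphericity holds; Mauchly p should not
        # pile up near zero
        assert np.mean(np.asarray(ps_m) < 0.05) < 0.15

    def test_ventral_effect_power(self, rng):
        hits = 0
        reps = 50
        for _ in range(reps):
            dat = synth.synth_regional_D(
                1.0, [0, 0, 0, 0, 2.0], 0.5, 14, seed=int(rng.integers(2**31))
            )
            hits += st.rm_anova(dat).within_p < 0.05
        assert hits / reps > 0.9

    def test_identical_columns_degenerate(self):
        arr = np.tile(np.arange(5.0)[:, None], (1, 5)) + 10.0
        res = st.rm_anova(arr)
        assert res.degenerate
        assert res.within_F == 0.0

    def test_incomplete_cases_dropped_with_warning(self, caplog):
        dat = synth.synth_regional_D(1.0, [0, 0, 0, 0, 1.0], 0.5, 10, seed=9)
        dat.iloc[0, 2] = np.nan
        with caplog.at_level("WARNING"):
            res = st.rm_anova(dat)
        assert res.n_subjects == 9
        assert "incomplete" in caplog.text


class TestSimpleAnova:
    def test_two_groups_F_equals_t_squared(self, rng):
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b"], 12), "y": rng.normal(0, 1, 24)}
        )
        res = st.one_way_anova(df, "y", "g")
        t = st.pooled_t_test(
            df.query("g == 'a'").y, df.query("g == 'b'").y
        )
        assert res["F"] == pytest.approx(t["t"] ** 2, abs=1e-10)
        assert res["p"] == pytest.approx(t["p"], abs=1e-10)

    def test_label_permutation_null_uniform(self, rng):
        y = rng.normal(0, 1, 30)
        ps = []
        for _ in range(200):
            g = rng.permutation(np.repeat(["a", "b", "c"], 10))
            ps.append(st.one_way_anova(pd.DataFrame({"g": g, "y": y}), "y", "g")["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            st.one_way_anova(pd.DataFrame({"g": ["a"] * 5, "y": range(5)}), "y", "g")


class TestTukey:
    def test_studentized_range_quantile(self):
        # classical table value: q(k=3, df=12, alpha=.05) = 3.77
        assert sps.studentized_range.ppf(0.95, 3, 12) == pytest.approx(3.77, abs=5e-3)

    def test_two_groups_matches_pooled_t_decision(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0.8, 1, 10)
            t = st.pooled_t_test(a, b)
            mse = (
                ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            ) / (len(a) + len(b) - 2)
            res = st.tukey_hsd(
                [a.mean(), b.mean()], mse, len(a) + len(b) - 2, [len(a), len(b)]
            )
            # for k = 2 the studentized-range p equals the two-sample t p
            assert res.p_matrix[0, 1] == pytest.approx(t["p"], abs=1e-6)

    def test_equal_means_no_rejections(self):
        res = st.tukey_hsd([5.0, 5.0, 5.0], 1.0, 12, [5, 5, 5])
        assert set(res.letters.values()) == {"a"}


class TestAssumptionPolicy:
    def test_pillai_recommended_when_box_m_rejects(self, rng):
        df = pd.DataFrame(
            {
                "g": np.repeat(["a", "b"], 25),
                "x": rng.normal(2, 0.5, 50),
                "y1": np.concatenate([rng.normal(0, 0.3, 25), rng.normal(0, 6, 25)]),
                "y2": np.concatenate([rng.normal(0, 0.3, 25), rng.normal(0, 6, 25)]),
            }
        )
        res = st.assumption_checks(df, ["y1", "y2"], "g", "x")
        assert res.box_p < 0.001
        assert res.recommended_criterion == "pillai"

    def test_wilks_kept_under_homoscedasticity(self, rng):
        df = pd.DataFrame(
            {
                "g": np.repeat(["a", "b"], 25),
                "x": rng.normal(2, 0.5, 50),
                "y1": rng.normal(0, 1, 50),
                "y2": rng.normal(0, 1, 50),
            }
        )
        res = st.assumption_checks(df, ["y1", "y2"], "g", "x")
        assert res.recommended_criterion == "wilks"
        assert res.slopes_wilks.p > 0.001
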