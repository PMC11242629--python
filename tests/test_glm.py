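import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glmqlmas import (
    SampleAnnotation,
    SimulationConfig,
    adjust_pvalues,
    build_design,
    de_analysis,
    drop_unexpressed,
    estimate_common_dispersion,
    fit_nb_glm,
    generate_cohort,
    ql_f_test,
    ql_moderate,
    tmm_normalize,
)
from glmqlmas.containers import IntegrityError
from glmqlmas.glm import GLMFit, _cox_reid_apl, fit_f_prior

RNG = np.random.default_rng(20240901)


def _two_group_design(n0, n1):
    x = np.r_[np.zeros(n0), np.ones(n1)]
    return np.column_stack([np.ones(n0 + n1), x])


def _annotation(n0, n1):
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n0 + n1)],
                "alnm_status": ["negative"] * n0 + ["positive"] * n1,
                "prior_chemo": False,
                "prior_radio": False,
            }
        )
    )


class TestBuildDesign:
    def test_two_plus_two_layout(self):
        d = build_design(_annotation(2, 2))
        np.testing.assert_array_equal(d.matrix[:, 0], 1)
        np.testing.assert_array_equal(d.group, [0, 0, 1, 1])

    def test_single_group_rejected(self):
        with pytest.raises(IntegrityError):
            build_design(_annotation(4, 0))

    def test_sample_permutation_permutes_rows(self):
        ann = _annotation(3, 2)
        order = ["s4", "s0", "s2", "s1", "s3"]
        d = build_design(ann, order)
        want = [1, 0, 0, 0, 1]
        np.testing.assert_array_equal(d.group, want)


class TestFitNBGLM:
    def test_group_coefficient_equals_log_mean_ratio_with_equal_offsets(self):
        y = np.array([10, 12, 8, 30, 28, 35, 27], dtype=float)
        X = _two_group_design(3, 4)
        off = np.zeros(7)
        fit = fit_nb_glm(y, X, off, 0.1)
        m0, m1 = y[:3].mean(), y[3:].mean()
        assert fit.coefficients[0, 1] == pytest.approx(np.log(m1 / m0), abs=1e-8)
        assert fit.coefficients[0, 0] == pytest.approx(np.log(m0), abs=1e-8)

    def test_poisson_limit_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 40
        X = _two_group_design(20, 20)
        off = np.log(rng.uniform(0.5e4, 2e4, n))
        y = rng.poisson(np.exp(off - 6.0 + 0.7 * X[:, 1]))
        fit = fit_nb_glm(y, X, off, 1e-12)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        np.testing.assert_allclose(fit.coefficients[0], ref.params, atol=1e-6)

    def test_identical_groups_give_zero_effect_and_zero_deviance_gain(self):
        y = np.array([5, 7, 6, 5, 7, 6], dtype=float)
        X = _two_group_design(3, 3)
        off = np.zeros(6)
        full = fit_nb_glm(y, X, off, 0.05)
        reduced = fit_nb_glm(y, X[:, :1], off, 0.05)
        assert full.coefficients[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert reduced.deviance[0] - full.deviance[0] == pytest.approx(0.0, abs=1e-10)

    def test_score_equations_satisfied(self):
        rng = np.random.default_rng(9)
        X = _two_group_design(12, 10)
        off = np.log(rng.uniform(1e3, 3e3, 22))
        Y = rng.poisson(rng.uniform(5, 200, (50, 1)) * np.exp(off - np.mean(off))[None, :])
        phi = 0.08
        fit = fit_nb_glm(Y, X, off, phi)
        mu = fit.fitted
        score = np.einsum("np,gn->gp", X, (Y - mu) / (1 + phi * mu))
        assert np.max(np.abs(score)) < 1e-6


class TestCommonDispersion:
    def _simulate(self, phi, n_genes=2000, n=40, seed=31):
        cfg = SimulationConfig(
            n_genes=n_genes, n_coding=n_genes, group_sizes=(n // 2, n - n // 2),
            de_fraction=0.0, dispersion=phi, seed=seed,
        )
        counts, samples, _, _ = generate_cohort(cfg)
        counts, _ = drop_unexpressed(counts)
        factors = tmm_normalize(counts)
        X = build_design(samples, counts.sample_ids)
        off = np.log(factors.effective_library_size)
        return counts.values.astype(float), X, off

    def test_poisson_data_estimates_near_zero(self):
        Y, X, off = self._simulate(0.0)
        assert estimate_common_dispersion(Y, X, off) <= 0.01

    def test_recovers_planted_dispersion(self):
        Y, X, off = self._simulate(0.1)
        assert 0.08 <= estimate_common_dispersion(Y, X, off) <= 0.12

    def test_matches_exhaustive_grid_on_tiny_fixture(self):
        Y, X, off = self._simulate(0.2, n_genes=60, n=16, seed=5)
        phi_hat = estimate_common_dispersion(Y, X, off)
        apl_hat, _ = _cox_reid_apl(Y, X.matrix, off, phi_hat)
        grid = np.exp(np.linspace(np.log(1e-8), np.log(10.0), 400))
        apl_grid = max(_cox_reid_apl(Y, X.matrix, off, g)[0] for g in grid)
        assert apl_hat >= apl_grid - 1e-6


class TestQLModeration:
    def test_equal_dispersions_are_a_fixed_point(self):
        dev = np.full(50, 3.0)
        fit = GLMFit(np.zeros((50, 2)), np.ones((50, 4)), dev, 2, np.ones(50, bool), 1)
        ql = ql_moderate(fit)
        np.testing.assert_allclose(ql.s2_post, 1.5, rtol=1e-9)

    def test_infinite_prior_collapses_to_common_value(self):
        # spread of log s2 below the chi-square floor -> d0 = inf
        rng = np.random.default_rng(12)
        dev = 2.0 * (1 + 0.001 * rng.normal(size=200))
        fit = GLMFit(np.zeros((200, 2)), np.ones((200, 4)), dev, 2, np.ones(200, bool), 1)
        ql = ql_moderate(fit)
        assert np.isinf(ql.prior_df)
        assert np.allclose(ql.s2_post, ql.prior_s2)

    def test_prior_df_recovery_from_scaled_f(self):
        """s2 ~ s2_true * chi2(df)/df with s2_true from a d0=10 inverse
        chi-square prior: moment matching recovers d0 in [5, 20]."""
        rng = np.random.default_rng(13)
        d0, df, G = 10.0, 30, 5000
        s2_true = 1.5 * d0 / rng.chisquare(d0, G)
        s2_obs = s2_true * rng.chisquare(df, G) / df
        d0_hat, _ = fit_f_prior(s2_obs, df)
        assert 5.0 <= d0_hat <= 20.0

    def test_moderated_value_lies_between_raw_and_prior(self):
        rng = np.random.default_rng(14)
        dev = rng.chisquare(5, 300)
        fit = GLMFit(np.zeros((300, 2)), np.ones((300, 8)), dev, 6, np.ones(300, bool), 1)
        ql = ql_moderate(fit)
        lo = np.minimum(ql.s2_raw, ql.prior_s2) - 1e-12
        hi = np.maximum(ql.s2_raw, ql.prior_s2) + 1e-12
        assert np.all((ql.s2_post >= lo) & (ql.s2_post <= hi))


class TestQLFTest:
    def _fits(self, dev_full, dev_reduced, df=10):
        G = len(dev_full)
        coef = np.zeros((G, 2))
        full = GLMFit(coef, np.ones((G, 2)), np.asarray(dev_full, float), df,
                      np.ones(G, bool), 1)
        red = GLMFit(coef[:, :1], np.ones((G, 2)), np.asarray(dev_reduced, float), df + 1,
                     np.ones(G, bool), 1)
        return full, red

    def test_zero_deviance_difference_gives_f_zero_p_one(self):
        full, red = self._fits(np.full(20, 4.0), np.full(20, 4.0))
        ql = ql_moderate(full)
        out = ql_f_test(full, red, ql)
        assert np.all(out["F"] == 0.0)
        assert np.all(out["p"] == 1.0)

    def test_f_is_linear_in_deviance_difference(self):
        full, red1 = self._fits(np.full(20, 2.0), np.full(20, 4.0))
        _, red2 = self._fits(np.full(20, 2.0), np.full(20, 6.0))
        ql = ql_moderate(full)
        f1 = ql_f_test(full, red1, ql)["F"].to_numpy()
        f2 = ql_f_test(full, red2, ql)["F"].to_numpy()
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_negative_deviance_difference_rejected(self):
        full, red = self._fits(np.full(20, 4.0), np.full(20, 3.0))
        ql = ql_moderate(full)
        with pytest.raises(IntegrityError):
            ql_f_test(full, red, ql)


class TestAdjustPvalues:
    def test_bh_step_up_worked_example(self):
        got = adjust_pvalues(np.array([0.01, 0.02, 0.03, 0.04]), "BH")
        np.testing.assert_allclose(got, 0.04, rtol=1e-15)

    def test_single_p_unchanged_under_bh(self):
        assert adjust_pvalues(np.array([0.37]), "BH")[0] == pytest.approx(0.37)

    def test_all_equal_p_unchanged_under_bh(self):
        got = adjust_pvalues(np.full(9, 0.2), "BH")
        np.testing.assert_allclose(got, 0.2, rtol=1e-15)

    def test_bonferroni_definition(self):
        p = np.array([0.001, 0.4, 0.9])
        np.testing.assert_allclose(adjust_pvalues(p, "bonferroni"), [0.003, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(IntegrityError):
            adjust_pvalues(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_bh_preserves_p_value_ordering(self, ps):
        p = np.asarray(ps)
        adj = adjust_pvalues(p, "BH")
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestDEAnalysisProperties:
    def test_label_swap_negates_lfc_and_preserves_f(self, small_cohort):
        counts, samples, _, _ = small_cohort
        factors = tmm_normalize(counts)
        de1 = de_analysis(counts, samples, factors)
        swapped = samples.table.copy()
        swapped["alnm_status"] = swapped["alnm_status"].map(
            {"positive": "negative", "negative": "positive"}
        )
        de2 = de_analysis(counts, SampleAnnotation(swapped), factors)
        np.testing.assert_allclose(de1["log2FC"], -de2["log2FC"], atol=1e-8)
        np.testing.assert_allclose(de1["F"], de2["F"], atol=1e-8)
        np.testing.assert_allclose(de1["p"], de2["p"], atol=1e-8)

    def test_adjusted_p_never_below_raw(self, small_de_table):
        de, _ = small_de_table
        assert np.all(de["p_BH"] >= de["p"] - 1e-15)
        assert np.all(de["p_bonf"] >= de["p"] - 1e-15)

    def test_direction_consistent_with_gates(self, small_de_table):
        de, _ = small_de_table
        up = de["direction"] == "up"
        assert np.all(de.loc[up, "log2FC"] > 1.0)
        assert np.all(de.loc[up, "p_BH"] < 0.05)
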