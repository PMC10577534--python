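import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import secretoclock as sc
from secretoclock.diffexpr import (
    DesignError,
    ModerationParams,
    build_design,
    estimate_precision_weights,
    ordinary_t,
)
from .conftest import make_two_group_matrix


def bh_oracle(p):
    """Hand step-up: adjusted p_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = min(running, 1.0)
    return adj


def _meta(genotypes, sexes=None, cohorts=None, models=None):
    n = len(genotypes)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "genotype": genotypes,
            "model": models or ["LmnaG609G"] * n,
            "sex": sexes or ["male"] * n,
            "cohort": cohorts or ["c1"] * n,
            "age_months": 5.0,
        }
    )


class TestBuildDesign:
    def test_genotype_only_treatment_coding(self):
        meta = _meta(["wildtype"] * 3 + ["progeroid"] * 3)
        d = build_design(meta, sc.DesignSpec(terms=["genotype"], contrast="genotype"))
        assert d.X.shape == (6, 2)
        np.testing.assert_array_equal(d.X[:, 1], [0, 0, 0, 1, 1, 1])
        assert d.contrast_index == 1

    def test_column_count_with_three_level_cohort(self):
        meta = _meta(
            ["wildtype", "progeroid"] * 3,
            sexes=["male", "male", "female", "female", "male", "female"],
            cohorts=["c1", "c1", "c2", "c2", "c3", "c3"],
        )
        d = build_design(meta, sc.DesignSpec(terms=["genotype", "sex", "cohort"], contrast="genotype"))
        assert d.X.shape[1] == 5  # intercept + genotype + sex + 2 cohort indicators

    def test_collinear_cohort_raises_naming_columns(self):
        meta = _meta(
            ["wildtype"] * 3 + ["progeroid"] * 3,
            cohorts=["c1"] * 3 + ["c2"] * 3,
        )
        with pytest.raises(DesignError, match="cohort"):
            build_design(meta, sc.DesignSpec(terms=["genotype", "cohort"], contrast="genotype"))

    def test_interaction_columns_are_products(self):
        meta = _meta(
            ["wildtype", "wildtype", "progeroid", "progeroid"],
            sexes=["male", "female", "male", "female"],
        )
        d = build_design(
            meta, sc.DesignSpec(terms=["genotype", "sex", "sex:genotype"], contrast="sex:genotype")
        )
        g = (meta["genotype"] == "progeroid").astype(float)
        m = (meta["sex"] == "male").astype(float)
        np.testing.assert_array_equal(d.X[:, d.contrast_index], (m * g).to_numpy())


class TestFitPerAptamer:
    def test_exact_two_group_fit(self):
        matrix, meta = make_two_group_matrix([1, 1, 1], [3, 3, 3])
        d = build_design(meta, sc.DesignSpec(terms=["genotype"], contrast="genotype"))
        fits = sc.fit_per_aptamer_lm(matrix, d)
        assert fits.coefficients[0, d.contrast_index] == pytest.approx(2.0)
        assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equation_oracle(self):
        # oracle: solve the 6x2 normal equations by direct matrix inversion
        rng = np.random.default_rng(11)
        y = rng.normal(size=6)
        meta = _meta(["wildtype"] * 3 + ["progeroid"] * 3)
        matrix = sc.ProteomeMatrix(pd.DataFrame({"a0": y}, index=list(meta["sample_id"])))
        d = build_design(meta, sc.DesignSpec(terms=["genotype"], contrast="genotype"))
        fits = sc.fit_per_aptamer_lm(matrix, d)
        X = d.X
        beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(fits.coefficients[0], beta_oracle, atol=1e-10)

    def test_permutation_invariance(self, small_cohorts):
        _, _, st_m, st_meta, _ = small_cohorts
        d = build_design(st_meta, sc.DesignSpec())
        fits = sc.fit_per_aptamer_lm(st_m, d)
        perm = np.random.default_rng(0).permutation(len(st_meta))
        meta_p = sc.SampleMetadata(st_meta.table.iloc[perm])
        m_p = sc.ProteomeMatrix(st_m.values.iloc[perm])
        fits_p = sc.fit_per_aptamer_lm(m_p, build_design(meta_p, sc.DesignSpec()))
        np.testing.assert_allclose(fits_p.coefficients, fits.coefficients, atol=1e-9)
        np.testing.assert_allclose(fits_p.sigma2, fits.sigma2, atol=1e-9)

    def test_ordinary_t_matches_textbook_oracle(self):
        # oracle: classical OLS t = beta_j / sqrt(s^2 (X'X)^-1_jj), p from t_df
        rng = np.random.default_rng(21)
        for _ in range(5):
            n = 12
            meta = _meta(
                list(rng.permutation(["wildtype"] * 6 + ["progeroid"] * 6)),
                sexes=list(rng.permutation(["male"] * 6 + ["female"] * 6)),
            )
            Y = rng.normal(size=(n, 4))
            matrix = sc.ProteomeMatrix(
                pd.DataFrame(Y, index=list(meta["sample_id"]), columns=[f"a{j}" for j in range(4)])
            )
            d = build_design(meta, sc.DesignSpec(terms=["genotype", "sex"], contrast="genotype"))
            fits = sc.fit_per_aptamer_lm(matrix, d)
            t, p = ordinary_t(fits)
            X, j, df = d.X, d.contrast_index, n - d.X.shape[1]
            xtx_inv = np.linalg.inv(X.T @ X)
            for g in range(4):
                beta = np.linalg.inv(X.T @ X) @ X.T @ Y[:, g]
                resid = Y[:, g] - X @ beta
                s2 = resid @ resid / df
                t_oracle = beta[j] / np.sqrt(s2 * xtx_inv[j, j])
                assert t[g] == pytest.approx(t_oracle, abs=1e-10)
                assert p[g] == pytest.approx(2 * stats.t.sf(abs(t_oracle), df), abs=1e-10)

    def test_log2fc_invariant_to_constant_shift(self):
        matrix, meta = make_two_group_matrix([1.0, 1.5, 0.5, 1.2], [2.8, 3.1, 3.0, 2.6])
        d = build_design(meta, sc.DesignSpec(terms=["genotype"], contrast="genotype"))
        f1 = sc.fit_per_aptamer_lm(matrix, d)
        shifted = sc.ProteomeMatrix(matrix.values + 7.0)
        f2 = sc.fit_per_aptamer_lm(shifted, d)
        assert f2.coefficients[0, d.contrast_index] == pytest.approx(
            f1.coefficients[0, d.contrast_index], abs=1e-12
        )


class TestPrecisionWeights:
    def _sim(self, mode, seed=0):
        cfg = sc.SimulationConfig(
            seed=seed, n_aptamers=400, frac_unmapped=0.0, n_ortholog_pairs=0, noise_mode=mode
        )
        panel = sc.simulate_panel(cfg)
        matrix, meta, truth = sc.simulate_progeria_cohorts(panel, cfg)
        design = build_design(meta, sc.DesignSpec())
        return matrix, design, truth

    def test_homoscedastic_weights_near_one(self):
        matrix, design, _ = self._sim("constant")
        w = estimate_precision_weights(matrix, design)
        assert (np.abs(w - 1.0) < 0.1).mean() >= 0.95

    def test_mean_dependent_variance_orders_weights(self):
        matrix, design, truth = self._sim("mean_dependent")
        w = estimate_precision_weights(matrix, design)
        baseline = truth.per_aptamer["baseline"].to_numpy()
        low_var = baseline < np.median(baseline)  # variance grows with baseline
        assert np.median(w[:, low_var]) > np.median(w[:, ~low_var])

    def test_constant_matrix_gives_unit_weights(self):
        n, p = 10, 60
        meta = _meta(["wildtype"] * 5 + ["progeroid"] * 5)
        matrix = sc.ProteomeMatrix(
            pd.DataFrame(np.full((n, p), 8.0), index=list(meta["sample_id"]),
                         columns=[f"a{j}" for j in range(p)])
        )
        design = build_design(meta, sc.DesignSpec(terms=["genotype"], contrast="genotype"))
        np.testing.assert_array_equal(estimate_precision_weights(matrix, design), 1.0)

    def test_too_few_aptamers_warns_and_returns_ones(self):
        matrix, meta = make_two_group_matrix([1, 2, 1.5], [3, 2.5, 3.2], n_aptamers=5)
        design = build_design(meta, sc.DesignSpec(terms=["genotype"], contrast="genotype"))
        with pytest.warns(UserWarning, match="fewer than 50"):
            w = estimate_precision_weights(matrix, design)
        np.testing.assert_array_equal(w, 1.0)


class TestModeration:
    def _fits(self, sigma2, df=4.0):
        """Minimal stand-in for LMFits with unit coefficients and se."""
        fits = type("Fits", (), {})()
        fits.sigma2 = np.asarray(sigma2, dtype=float)
        fits.df = df
        fits.coefficients = np.ones((len(fits.sigma2), 2))
        fits.unscaled_se = np.ones((len(fits.sigma2), 2))
        fits.design = type("D", (), {"contrast_index": 1})()
        return fits

    def test_posterior_variance_formula(self):
        # oracle: direct evaluation of (d0 s0^2 + df s^2) / (d0 + df)
        fits = self._fits([1.0, 4.0], df=4.0)
        params = ModerationParams(d0=4.0, s0_sq=2.0)
        _, t, _ = sc.moderate_variances(fits, params)
        s2_post = (4.0 * 2.0 + 4.0 * fits.sigma2) / 8.0
        np.testing.assert_allclose(s2_post, [1.5, 3.0])
        np.testing.assert_allclose(t, 1.0 / np.sqrt(s2_post))

    def test_infinite_prior_df_shrinks_fully_to_prior(self):
        fits = self._fits([2.0] * 12, df=6.0)
        params = ModerationParams(d0=np.inf, s0_sq=2.0)
        _, t, p = sc.moderate_variances(fits, params)
        np.testing.assert_allclose(t, 1.0 / np.sqrt(2.0))
        np.testing.assert_allclose(p, 2 * stats.norm.sf(1.0 / np.sqrt(2.0)), rtol=1e-12)

    def test_zero_prior_df_equals_ordinary_t(self):
        rng = np.random.default_rng(3)
        fits = self._fits(rng.uniform(0.5, 2.0, size=20), df=5.0)
        params = ModerationParams(d0=1e-300, s0_sq=1.0)
        _, t_mod, _ = sc.moderate_variances(fits, params)
        t_ord, _ = ordinary_t(fits)
        np.testing.assert_allclose(t_mod, t_ord, rtol=1e-6)

    def test_estimated_prior_recovers_simulation(self):
        # s^2 drawn from the scaled-F model with known d0, s0
        rng = np.random.default_rng(9)
        d0_true, s0_true, df = 8.0, 0.25, 10.0
        n = 5000
        true_var = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = true_var * rng.chisquare(df, size=n) / df
        fits = self._fits(s2, df=df)
        params, _, _ = sc.moderate_variances(fits)
        assert params.d0 == pytest.approx(d0_true, rel=0.25)
        assert params.s0_sq == pytest.approx(s0_true, rel=0.1)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.2, 0.9], [0.015, 0.3, 0.9]),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        np.testing.assert_allclose(sc.bh_adjust(np.array(p)), expected, atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            sc.bh_adjust(np.array([0.1, np.nan]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(sc.bh_adjust(np.array(p)), bh_oracle(p), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=100)
        adj = sc.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestRunDE:
    def test_summary_arithmetic(self):
        assert sc.summarize_counts(2119, 356) == {
            "n_de": 2475, "n_up": 356, "n_down": 2119, "pct_down": 85.6, "pct_up": 14.4,
        }

    def test_summary_consistency_on_simulation(self, small_cohorts):
        _, _, st_m, st_meta, _ = small_cohorts
        table, summary = sc.run_de(st_m, st_meta)
        assert summary["n_de"] == summary["n_up"] + summary["n_down"]
        assert summary["n_de"] == int(table["is_de"].sum())
        if summary["n_de"]:
            assert summary["pct_down"] == round(100 * summary["n_down"] / summary["n_de"], 1)

    def test_null_pvalues_uniform(self):
        cfg = sc.SimulationConfig(
            seed=123, n_aptamers=2000, frac_unmapped=0.0, n_ortholog_pairs=0,
            aging=sc.AgingConfig(frac_age_associated=0.0),
            case_control=sc.CaseControlConfig(frac_de=0.0, n_interaction_proteins=0,
                                              batch_shift_sd=0.0),
        )
        panel = sc.simulate_panel(cfg)
        matrix, meta, _ = sc.simulate_progeria_cohorts(panel, cfg)
        table, _ = sc.run_de(matrix, meta)
        assert stats.kstest(table["p"], "uniform").pvalue > 0.001

    def test_false_discovery_proportion_controlled(self):
        # oracle: generator truth labels; average FDP over 20 seeds <= 0.10
        fdps = []
        for seed in range(20):
            cfg = sc.SimulationConfig(seed=seed, n_aptamers=500, frac_unmapped=0.0,
                                      n_ortholog_pairs=0)
            panel = sc.simulate_panel(cfg)
            matrix, meta, truth = sc.simulate_progeria_cohorts(panel, cfg)
            table, _ = sc.run_de(matrix, meta)
            t = truth.per_aptamer.set_index("aptamer_id")
            is_null = (
                (t.loc[table["aptamer_id"], "effect_lmna"] == 0)
                & (t.loc[table["aptamer_id"], "age_slope"] == 0)
                & ~t.loc[table["aptamer_id"], "is_interaction"]
            ).to_numpy()
            called = table["is_de"].to_numpy()
            fdps.append((called & is_null).sum() / max(called.sum(), 1))
        assert np.mean(fdps) <= 0.10


class TestInteraction:
    def _sim(self, seed, n_inter, effect=1.5):
        cfg = sc.SimulationConfig(
            seed=seed, n_aptamers=300, frac_unmapped=0.0, n_ortholog_pairs=0, noise_sd=0.3,
            case_control=sc.CaseControlConfig(
                frac_de=0.1, n_interaction_proteins=n_inter, interaction_effect=effect
            ),
        )
        panel = sc.simulate_panel(cfg)
        matrix, meta, truth = sc.simulate_progeria_cohorts(panel, cfg)
        return matrix, meta, truth

    def test_injected_interactions_recovered(self):
        recovered = []
        for seed in range(20):
            matrix, meta, truth = self._sim(seed, n_inter=5)
            table = sc.test_interaction(matrix, meta)
            hits = set(table.loc[table["is_de"], "aptamer_id"])
            injected = set(
                truth.per_aptamer.loc[truth.per_aptamer["is_interaction"], "aptamer_id"]
            )
            recovered.append(len(hits & injected))
        assert np.median(recovered) >= 4

    def test_no_injected_interactions_rarely_called(self):
        clean = 0
        for seed in range(20):
            matrix, meta, _ = self._sim(seed + 100, n_inter=0)
            table = sc.test_interaction(matrix, meta)
            clean += int(table["is_de"].sum() == 0)
        assert clean >= 18

    def test_sex_swap_negates_coefficient(self):
        matrix, meta, _ = self._sim(0, n_inter=3)
        t1 = sc.test_interaction(matrix, meta, weights=False)
        swapped = meta.table.copy()
        swapped["sex"] = swapped["sex"].map({"male": "female", "female": "male"})
        t2 = sc.test_interaction(matrix, sc.SampleMetadata(swapped), weights=False)
        np.testing.assert_allclose(t2["log2FC"], -t1["log2FC"], atol=1e-9)
        np.testing.assert_allclose(t2["p"], t1["p"], atol=1e-9)

    def test_single_sex_rejected(self):
        matrix, meta = make_two_group_matrix([1, 2, 1], [3, 2, 3])
        tbl = meta.table.copy()
        tbl["sex"] = "male"
        with pytest.raises(DesignError, match="both sexes"):
            sc.test_interaction(matrix, sc.SampleMetadata(tbl))
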