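import dataclasses
import logging

import numpy as np
import pytest

from hilasso import (
    Dataset,
    HiLassoConfig,
    aggregate_beta,
    compute_num_bootstraps,
    draw_bootstrap,
    fit_hilasso,
    importance_from_coefs,
    run_procedure,
)
from hilasso.solvers import SolverConfig, standardize, fit_elastic_net

from conftest import coef_matrix_from_values
from oracle_utils import masked_abs_mean


class TestComputeNumBootstraps:
    @pytest.mark.parametrize(
        "L,p,q,expected",
        [(30, 100, 50, 60), (1, 5, 5, 1), (30, 10000, 200, 1500), (30, 100, 100, 30),
         (7, 10, 3, 24)],
    )
    def test_ceiling_formula(self, L, p, q, expected):
        assert compute_num_bootstraps(L, p, q) == expected

    @pytest.mark.parametrize("L,p,q", [(30, 5, 6), (30, 5, 0), (0, 5, 5)])
    def test_invalid_arguments(self, L, p, q):
        with pytest.raises(ValueError):
            compute_num_bootstraps(L, p, q)

    def test_expected_selection_count_at_least_L(self):
        # uniform q-of-p sampling over B draws: E[selections] = B*q/p >= L
        for L, p, q in [(30, 100, 50), (30, 997, 61), (5, 12, 7)]:
            B = compute_num_bootstraps(L, p, q)
            assert B * q / p >= L
            assert (B - 1) * q / p < L  # and B is the smallest such integer


class TestDrawBootstrap:
    def test_q_equals_p_selects_everything(self):
        draw = draw_bootstrap(10, 6, 6, probs=np.array([0.9, 0.02, 0.02, 0.02, 0.02, 0.02]), seed=0)
        np.testing.assert_array_equal(draw.col_idx, np.arange(6))

    def test_same_seed_gives_identical_draw(self):
        a = draw_bootstrap(20, 15, 5, seed=42)
        b = draw_bootstrap(20, 15, 5, seed=42)
        np.testing.assert_array_equal(a.row_idx, b.row_idx)
        np.testing.assert_array_equal(a.col_idx, b.col_idx)

    def test_draw_shapes_and_distinctness(self):
        draw = draw_bootstrap(25, 40, 12, seed=3)
        assert draw.row_idx.shape == (25,)
        assert draw.col_idx.shape == (12,)
        assert np.unique(draw.col_idx).size == 12

    def test_weighted_selection_frequency_matches_probs(self):
        # q=1 draws from probs (0.7, 0.1, 0.1, 0.1): selection frequency of
        # predictor 1 should match 0.7 within Monte-Carlo error
        probs = np.array([0.7, 0.1, 0.1, 0.1])
        hits = sum(
            draw_bootstrap(2, 4, 1, probs=probs, seed=s).col_idx[0] == 0
            for s in range(30000)
        )
        freq = hits / 30000
        assert abs(freq - 0.7) < 0.01  # ~4 MC sd

    def test_more_positive_probs_than_q_required(self):
        probs = np.array([0.5, 0.5, 0.0, 0.0])
        with pytest.raises(ValueError, match="positive probability"):
            draw_bootstrap(5, 4, 3, probs=probs, seed=0)


class TestRunProcedure:
    def test_single_full_draw_equals_plain_fit(self, small_dataset):
        data, _ = small_dataset
        cfg = SolverConfig()
        coef = run_procedure(
            data, data.p, 1, solver="elastic_net", cfg=cfg, master_seed=5,
            resample_rows=False,
        )
        sdata = standardize(data.X, data.y)
        # reproduce the per-draw CV seed derivation for draw 0 of stage 1
        child = np.random.SeedSequence(entropy=5, spawn_key=(1, 0))
        _, s_cv = child.generate_state(2)
        direct = fit_elastic_net(sdata, cfg, int(s_cv) % (2**31))
        np.testing.assert_allclose(coef.values[:, 0], direct, atol=1e-12)

    def test_missing_pattern_matches_recorded_draws(self, small_dataset):
        data, _ = small_dataset
        coef = run_procedure(data, 4, 12, solver="elastic_net", master_seed=9)
        coef.validate()
        for b, draw in enumerate(coef.draws):
            expected = np.zeros(data.p, dtype=bool)
            expected[draw.col_idx] = True
            np.testing.assert_array_equal(~coef.missing_mask[:, b], expected)

    def test_result_independent_of_n_jobs(self, small_dataset):
        data, _ = small_dataset
        a = run_procedure(data, 5, 8, solver="elastic_net", master_seed=3, n_jobs=1)
        b = run_procedure(data, 5, 8, solver="elastic_net", master_seed=3, n_jobs=4)
        np.testing.assert_array_equal(a.values, b.values)

    def test_solver_failure_reports_draw_index(self, rng):
        X = rng.standard_normal((12, 4))
        X[:, 2] = 1.0  # constant column -> standardization error inside the draw
        data = Dataset(X=X, y=rng.normal(size=12))
        with pytest.raises(RuntimeError, match="bootstrap draw 0"):
            run_procedure(data, 4, 1, solver="elastic_net", master_seed=0)


class TestImportance:
    def test_mean_of_absolute_values(self):
        values = np.full((2, 3), np.nan)
        values[0, 0], values[0, 1] = 1.0, -0.5
        values[1, 2] = 2.0
        imp = importance_from_coefs(coef_matrix_from_values(values))
        assert imp.scores[0] == pytest.approx(0.75)

    def test_never_sampled_predictor_gets_floor(self):
        values = np.full((3, 2), np.nan)
        values[0] = [1.0, 2.0]
        values[1] = [0.5, np.nan]
        imp = importance_from_coefs(coef_matrix_from_values(values), floor_eps=1e-10)
        assert imp.scores[2] == pytest.approx(1.5e-10)  # relative to max score
        assert imp.probs[2] > 0
        assert imp.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_loop_oracle_on_random_mask(self, random_masked_matrix):
        imp = importance_from_coefs(random_masked_matrix)
        expected = masked_abs_mean(random_masked_matrix.values)
        present = expected > 0
        np.testing.assert_allclose(imp.scores[present], expected[present], atol=1e-12)

    def test_probs_monotone_in_scores(self, random_masked_matrix):
        imp = importance_from_coefs(random_masked_matrix)
        order = np.argsort(imp.scores)
        assert np.all(np.diff(imp.probs[order]) >= 0)

    def test_all_missing_plan_rejected(self):
        values = np.full((3, 2), np.nan)
        with pytest.raises(ValueError, match="degenerate"):
            importance_from_coefs(coef_matrix_from_values(values))


class TestAggregateBeta:
    def test_signed_mean_over_occurrences(self):
        values = np.full((1, 4), np.nan)
        values[0, 0], values[0, 2] = 1.0, -0.5
        beta = aggregate_beta(coef_matrix_from_values(values))
        assert beta[0] == pytest.approx(0.25)

    def test_never_sampled_is_missing_with_warning(self, caplog):
        values = np.full((2, 3), np.nan)
        values[0] = [1.0, 1.0, 1.0]
        with caplog.at_level(logging.WARNING, logger="hilasso.core"):
            beta = aggregate_beta(coef_matrix_from_values(values))
        assert np.isnan(beta[1])
        assert "never sampled" in caplog.text

    def test_full_matrix_reduces_to_row_mean(self, rng):
        values = rng.normal(size=(4, 6))
        beta = aggregate_beta(coef_matrix_from_values(values))
        np.testing.assert_allclose(beta, values.mean(axis=1), atol=1e-12)


class TestFitHiLasso:
    def test_support_recovery_on_strong_signal(self, small_dataset):
        data, beta = small_dataset
        fit = fit_hilasso(data, HiLassoConfig(random_state=1))
        np.testing.assert_array_equal(np.flatnonzero(fit.selected), [0, 1, 2])

    def test_reproducible_under_same_random_state(self, small_dataset):
        data, _ = small_dataset
        a = fit_hilasso(data, HiLassoConfig(random_state=11))
        b = fit_hilasso(data, HiLassoConfig(random_state=11))
        np.testing.assert_array_equal(a.beta_hat, b.beta_hat)
        np.testing.assert_array_equal(a.test.pvalue, b.test.pvalue)
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_intermediates_are_consistent(self, small_dataset):
        data, _ = small_dataset
        fit = fit_hilasso(data, HiLassoConfig(random_state=2, q1=6, q2=6, L=5))
        assert fit.B1 == compute_num_bootstraps(5, data.p, 6)
        assert fit.B2 == compute_num_bootstraps(5, data.p, 6)
        fit.coef1.validate()
        fit.coef2.validate()
        # pooling identity: pi0 recomputed from coef2 equals the stored one
        k = (~fit.coef2.missing_mask).sum(axis=1)
        d = ((~fit.coef2.missing_mask) & (np.abs(np.nan_to_num(fit.coef2.values)) > 0)).sum(axis=1)
        assert fit.test.pi0 == pytest.approx(d.sum() / k.sum())

    def test_minimum_coverage_with_default_L(self, small_dataset):
        # P(zero selections) ~ e^-L per predictor; with L=30 every
        # predictor is sampled in both procedures in practice
        data, _ = small_dataset
        fit = fit_hilasso(data, HiLassoConfig(random_state=3))
        assert (~fit.coef1.missing_mask).sum(axis=1).min() >= 1
        assert (~fit.coef2.missing_mask).sum(axis=1).min() >= 1
        assert not fit.never_sampled.any()

    def test_config_validation(self, small_dataset):
        data, _ = small_dataset
        with pytest.raises(ValueError, match="q1"):
            fit_hilasso(data, HiLassoConfig(q1=data.p + 1))
        with pytest.raises(ValueError):
            HiLassoConfig(alpha=1.5)
        with pytest.raises(ValueError):
            HiLassoConfig(L=0)

    def test_logistic_mode_runs_and_selects(self, rng):
        X = rng.standard_normal((80, 8))
        logit = X[:, 0] * 3 - X[:, 1] * 3
        y = (rng.random(80) < 1 / (1 + np.exp(-logit))).astype(float)
        data = Dataset(X=X, y=y)
        # default L: with only a handful of draws the binomial test has
        # too few trials per predictor to ever reject
        fit = fit_hilasso(data, HiLassoConfig(logistic=True, random_state=0))
        assert np.all(np.isfinite(fit.test.pvalue))
        assert fit.selected[0] and fit.selected[1]
        assert fit.selected.sum() <= 4
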