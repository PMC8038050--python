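"""OLS fitting and the validation statistic battery."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nmtqsar as q
from conftest import random_regression

MODEL1_BLOCK = q.ValidationReport(
    r2tr=0.788, r2adj=0.781, lof=0.831, kxx=0.296, delta_k=0.063,
    rmse_tr=0.853, mae_tr=0.699, rss_tr=112.659, ccc_tr=0.882, s=0.87,
    f_stat=110.953, q2_loo=0.77, rmse_cv=0.89, mae_cv=0.729,
    press_cv=122.628, ccc_cv=0.871, q2_lmo=0.764, r2_yscr=0.033,
    q2_yscr=-0.047, rmse_ex=0.907, mae_ex=0.743, press_ext=126.77,
    r2_ex=0.757, q2_f1=0.755, q2_f2=0.755, q2_f3=0.76, ccc_ex=0.867,
    gt=q.GTRecord(k=0.998, k_prime=0.973, ro2=0.755, r_prime_o2=0.714,
                  r2m=0.723, r_prime_2m=0.6, r2=0.757),
)


class TestFitOls:
    def test_constant_response(self, rng):
        X = rng.normal(size=(20, 3))
        model = q.fit_ols(X, np.full(20, 4.2))
        assert model.intercept == pytest.approx(4.2, abs=1e-10)
        assert all(abs(b) < 1e-10 for b in model.coefficients.values())

    def test_noiseless_planted_recovery(self, rng):
        X = rng.normal(size=(25, 4))
        beta = np.array([0.5, -1.2, 2.0, 0.0])
        model = q.fit_ols(X, 3.0 + X @ beta)
        np.testing.assert_allclose(list(model.coefficients.values()), beta, atol=1e-8)
        assert model.intercept == pytest.approx(3.0, abs=1e-8)

    def test_against_hand_normal_equations(self):
        """5x2 hand dataset: coefficients equal the normal-equations solve."""
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 2.0], [5.0, 5.0]])
        y = np.array([2.1, 2.9, 5.2, 5.8, 8.0])
        Z = np.column_stack([np.ones(5), X])
        beta_hand = np.linalg.solve(Z.T @ Z, Z.T @ y)
        model = q.fit_ols(X, y)
        np.testing.assert_allclose(
            [model.intercept, *model.coefficients.values()], beta_hand, atol=1e-10)

    def test_halfwidths_are_95pct_t_intervals(self, rng):
        X, y, _ = random_regression(rng, n=40, p=3)
        model = q.fit_ols(X, y)
        # reconstruct from first principles
        Z = np.column_stack([np.ones(40), X])
        cov = np.linalg.inv(Z.T @ Z)
        resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        s2 = (resid**2).sum() / (40 - 3 - 1)
        se = np.sqrt(s2 * np.diag(cov))[1:]
        t = stats.t.ppf(0.975, 40 - 3 - 1)
        np.testing.assert_allclose(
            list(model.coef_halfwidths.values()), t * se, rtol=1e-8)

    def test_rank_deficiency_raises(self, rng):
        a = rng.normal(size=20)
        with pytest.raises(np.linalg.LinAlgError):
            q.fit_ols(np.column_stack([a, 2 * a]), rng.normal(size=20))

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            q.fit_ols(rng.normal(size=(4, 3)), rng.normal(size=4))


class TestPredict:
    def test_published_intercepts_at_zero_vector(self):
        zero = {n: 0.0 for n in q.NAMED_DESCRIPTORS}
        assert q.predict(q.MODEL_1, zero) == pytest.approx(0.928)
        assert q.predict(q.MODEL_2, zero) == pytest.approx(1.574)

    def test_published_arithmetic(self):
        x = {"C_AbSA": 100.0, "all_HASA2": 100.0, "fNH4B": 0.0,
             "fringNH2A": 0.0, "flipoH3B": 0.0}
        assert q.predict(q.MODEL_1, x) == pytest.approx(0.928 + 2.8 + 0.9, abs=1e-12)

    def test_missing_descriptor_raises(self):
        with pytest.raises(KeyError, match="fNH4B"):
            q.predict(q.MODEL_1, {"C_AbSA": 1.0})


class TestFitStatistics:
    def test_definitional_identities(self, rng):
        """RMSE, MAE, s, F, R²adj recomputed from RSS/TSS agree with their
        direct definitions to 1e-12."""
        X, y, _ = random_regression(rng, n=60, p=4)
        model = q.fit_ols(X, y)
        rep = q.basic_fit_stats(model, X, y)
        resid = y - q.predict_many(model, X)
        rss = (resid**2).sum()
        tss = ((y - y.mean()) ** 2).sum()
        n, p = 60, 4
        assert rep.rss_tr == pytest.approx(rss, abs=1e-12 * rss)
        assert rep.rmse_tr == pytest.approx(np.sqrt(rss / n), abs=1e-12)
        assert rep.mae_tr == pytest.approx(np.abs(resid).mean(), abs=1e-12)
        assert rep.s == pytest.approx(np.sqrt(rss / (n - p - 1)), abs=1e-12)
        assert rep.r2adj == pytest.approx(
            1 - (1 - rep.r2tr) * (n - 1) / (n - p - 1), abs=1e-12)
        assert rep.f_stat == pytest.approx(
            (rep.r2tr / p) / ((1 - rep.r2tr) / (n - p - 1)), abs=1e-9)
        assert rep.rss_tr == pytest.approx(n * rep.rmse_tr**2, rel=1e-12)

    def test_molecule_order_invariance(self, rng):
        X, y, _ = random_regression(rng, n=50, p=3)
        model = q.fit_ols(X, y)
        rep1 = q.basic_fit_stats(model, X, y)
        perm = rng.permutation(50)
        rep2 = q.basic_fit_stats(model, X[perm], y[perm])
        for f in ("r2tr", "rmse_tr", "mae_tr", "ccc_tr", "s"):
            assert getattr(rep1, f) == pytest.approx(getattr(rep2, f), rel=1e-12)


class TestLeaveOneOut:
    def test_noiseless_data_gives_q2_one(self, rng):
        X = rng.normal(size=(20, 3))
        y = 1.0 + X @ np.array([1.0, 2.0, -0.5])
        loo = q.q2_loo(X, y)
        assert loo.q2 == pytest.approx(1.0, abs=1e-10)
        assert loo.press == pytest.approx(0.0, abs=1e-12)

    def test_hat_identity_equals_explicit_refit(self, rng):
        """The hat-matrix LOO shortcut equals the n-refit loop elementwise."""
        X, y, _ = random_regression(rng, n=30, p=3)
        y_loo = q.validation.loo_predictions(X, y)
        Z = np.column_stack([np.ones(30), X])
        for i in range(30):
            mask = np.ones(30, dtype=bool)
            mask[i] = False
            beta = np.linalg.lstsq(Z[mask], y[mask], rcond=None)[0]
            assert y_loo[i] == pytest.approx(Z[i] @ beta, abs=1e-10)

    def test_q2_below_r2_on_noisy_fit(self, rng):
        X, y, _ = random_regression(rng, n=40, p=3, sigma=1.0)
        model = q.fit_ols(X, y)
        rep = q.basic_fit_stats(model, X, y)
        loo = q.q2_loo(X, y)
        assert loo.q2 < rep.r2tr


class TestLeaveManyOut:
    def test_noiseless_gives_one(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        assert q.q2_lmo(X, y, reps=50, seed=0) == pytest.approx(1.0, abs=1e-10)

    def test_zero_frac_out_rejected(self, rng):
        X, y, _ = random_regression(rng)
        with pytest.raises(ValueError):
            q.q2_lmo(X, y, frac_out=0.0, reps=100)

    def test_close_to_loo_on_well_conditioned_data(self, rng):
        X, y, _ = random_regression(rng, n=80, p=3, sigma=0.5)
        lmo = q.q2_lmo(X, y, reps=300, seed=1)
        loo = q.q2_loo(X, y)
        assert lmo <= loo.q2 + 0.05

    def test_seeded_reproducibility(self, rng):
        X, y, _ = random_regression(rng, n=50, p=3, sigma=0.8)
        assert q.q2_lmo(X, y, reps=100, seed=7) == q.q2_lmo(X, y, reps=100, seed=7)


class TestYScrambling:
    def test_destroys_planted_signal(self, rng):
        X, y, _ = random_regression(rng, n=100, p=5, sigma=0.3)
        model = q.fit_ols(X, y)
        rep = q.basic_fit_stats(model, X, y)
        loo = q.q2_loo(X, y)
        r2s, q2s = q.y_scramble(X, y, reps=200, seed=0)
        assert r2s < rep.r2tr
        assert q2s < loo.q2

    def test_reps_floor(self, rng):
        X, y, _ = random_regression(rng)
        with pytest.raises(ValueError):
            q.y_scramble(X, y, reps=50)

    def test_seeded_reproducibility(self, rng):
        X, y, _ = random_regression(rng, n=50, p=4)
        assert q.y_scramble(X, y, reps=100, seed=3) == q.y_scramble(X, y, reps=100, seed=3)


class TestExternalStats:
    def test_perfect_predictions(self, rng):
        X, y, _ = random_regression(rng, n=40, p=2, sigma=0.0)
        model = q.fit_ols(X, y)
        Xe = rng.normal(size=(15, 2))
        ye = q.predict_many(model, Xe)
        rep = q.external_stats(model, Xe, ye)
        for f in ("q2_f1", "q2_f2", "q2_f3", "ccc_ex"):
            assert getattr(rep, f) == pytest.approx(1.0, abs=1e-10)
        assert rep.rmse_ex == pytest.approx(0.0, abs=1e-10)

    def test_q2f2_never_exceeds_q2f1(self, rng):
        """The external mean minimizes the centering, so Q²F2 ≤ Q²F1."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y, _ = random_regression(r, n=50, p=3, sigma=1.0)
            model = q.fit_ols(X[:30], y[:30])
            rep = q.external_stats(model, X[30:], y[30:])
            assert rep.q2_f2 <= rep.q2_f1 + 1e-12

    def test_empty_external_set(self, rng):
        X, y, _ = random_regression(rng)
        model = q.fit_ols(X, y)
        with pytest.raises(ValueError, match="empty"):
            q.external_stats(model, np.empty((0, 3)), np.empty(0))


class TestGolbraikhTropsha:
    def test_identity_line(self, rng):
        y = rng.normal(size=20)
        gt = q.golbraikh_tropsha(y, y)
        assert gt.k == pytest.approx(1.0)
        assert gt.k_prime == pytest.approx(1.0)
        assert gt.r2m == pytest.approx(1.0)

    def test_scaling(self, rng):
        y = rng.uniform(1, 5, size=20)
        gt = q.golbraikh_tropsha(y, 2.0 * y)
        assert gt.k == pytest.approx(0.5)
        assert gt.k_prime == pytest.approx(2.0)

    def test_against_from_scratch_oracle(self, rng):
        """Random 20-point instance matches an independent origin-regression
        implementation to 1e-10."""
        y = rng.normal(2, 1, 20)
        yp = y + rng.normal(0, 0.4, 20)
        gt = q.golbraikh_tropsha(y, yp)
        k = (y * yp).sum() / (yp**2).sum()
        kp = (y * yp).sum() / (y**2).sum()
        ro2 = 1 - ((y - k * yp) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        rpo2 = 1 - ((yp - kp * y) ** 2).sum() / ((yp - yp.mean()) ** 2).sum()
        r2 = np.corrcoef(y, yp)[0, 1] ** 2
        assert gt.k == pytest.approx(k, abs=1e-10)
        assert gt.k_prime == pytest.approx(kp, abs=1e-10)
        assert gt.ro2 == pytest.approx(ro2, abs=1e-10)
        assert gt.r_prime_o2 == pytest.approx(rpo2, abs=1e-10)
        assert gt.r2m == pytest.approx(r2 * (1 - np.sqrt(abs(r2 - ro2))), abs=1e-10)

    def test_ccc_bounds(self, rng):
        x = rng.normal(size=30)
        assert q.ccc(x, x) == pytest.approx(1.0)
        assert q.ccc(x, -x) < 0


class TestKxx:
    def test_rank_one_limit(self, rng):
        a = rng.normal(size=30)
        kxx, _ = q.kxx_delta_k(np.column_stack([a, 3 * a]), rng.normal(size=30))
        assert kxx == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_columns_give_zero(self, rng):
        m = rng.normal(size=(50, 3))
        qmat, _ = np.linalg.qr(m - m.mean(0))
        kxx, _ = q.kxx_delta_k(qmat, rng.normal(size=50))
        assert kxx == pytest.approx(0.0, abs=1e-10)

    def test_matches_eigenvalue_oracle(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        kxx, dk = q.kxx_delta_k(X, y)
        lam = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))
        p = 4
        oracle = np.abs(lam / lam.sum() - 1 / p).sum() / (2 * (p - 1) / p)
        assert kxx == pytest.approx(oracle, abs=1e-12)
        lam2 = np.linalg.eigvalsh(np.corrcoef(np.column_stack([X, y]), rowvar=False))
        p2 = 5
        oracle_xy = np.abs(lam2 / lam2.sum() - 1 / p2).sum() / (2 * (p2 - 1) / p2)
        assert dk == pytest.approx(oracle_xy - oracle, abs=1e-12)

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        with pytest.raises(ValueError):
            q.kxx_delta_k(X, rng.normal(size=20))


class TestWilliamsAD:
    def test_training_leverages_sum_to_p_plus_one(self, rng):
        X, y, _ = random_regression(rng, n=50, p=4)
        model = q.fit_ols(X, y)
        ad = q.williams_ad(model, X, y)
        assert ad.leverages.sum() == pytest.approx(5.0, abs=1e-10)
        assert ad.leverages.mean() == pytest.approx(5 / 50, abs=1e-10)

    def test_h_star_formula(self, rng):
        X, y, _ = random_regression(rng, n=50, p=4)
        ad = q.williams_ad(q.fit_ols(X, y), X, y)
        assert ad.h_star == pytest.approx(3 * 5 / 50)
        assert q.leverage_cutoff(5, 155) == pytest.approx(18 / 155)

    def test_constructed_outlier_flagged_influential(self, rng):
        X, y, _ = random_regression(rng, n=40, p=3)
        model = q.fit_ols(X, y)
        far = np.full((1, 3), 25.0)  # far outside the descriptor cloud
        ad = q.williams_ad(model, X, y, X_ext=far, y_ext=np.array([0.0]),
                           ids_ext=["far"])
        assert "far" in ad.influential
        assert ad.leverages[-1] > ad.h_star

    def test_standardized_residuals_use_sigma(self, rng):
        X, y, _ = random_regression(rng, n=40, p=3, sigma=1.0)
        model = q.fit_ols(X, y)
        ad = q.williams_ad(model, X, y)
        resid = y - q.predict_many(model, X)
        np.testing.assert_allclose(ad.std_residuals, resid / model.sigma, atol=1e-12)


class TestAcceptanceCheck:
    def test_published_model1_block_passes_every_rule(self):
        result = q.acceptance_check(MODEL1_BLOCK)
        assert result.passed
        assert result.failing() == []

    @pytest.mark.parametrize("field,value,rule", [
        ("q2_loo", 0.4, "Q2loo >= 0.5"),
        ("q2_lmo", 0.55, "Q2LMO >= 0.6"),
        ("delta_k", 0.01, "deltaK >= 0.05"),
        ("ccc_ex", 0.7, "CCCex >= 0.80"),
        ("q2_f3", 0.5, "Q2F3 >= 0.60"),
    ])
    def test_single_rule_perturbations_fail_only_that_rule(self, field, value, rule):
        import dataclasses
        rep = dataclasses.replace(MODEL1_BLOCK)
        setattr(rep, field, value)
        result = q.acceptance_check(rep)
        assert not result.passed
        assert result.failing() == [rule]

    def test_rmse_ordering_rule(self):
        import dataclasses
        rep = dataclasses.replace(MODEL1_BLOCK)
        rep.rmse_tr, rep.rmse_cv = 0.9, 0.85
        result = q.acceptance_check(rep)
        assert result.failing() == ["RMSEtr < RMSEcv"]

    def test_missing_fields_listed_by_name(self):
        with pytest.raises(ValueError, match="q2_lmo"):
            q.acceptance_check(q.ValidationReport(r2tr=0.8))
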