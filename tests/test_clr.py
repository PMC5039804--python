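"""Conditional-likelihood-ratio updating: density ratios, Bayes updates,
closed forms, and parameter recovery."""

import numpy as np
import pytest

from riskupdate import (
    ClrUpdater,
    ConditionalMarkerModel,
    Dataset,
    LogisticModel,
    fit_clr,
    fit_clr_simple,
    likelihood_ratio,
    update_prediction,
)
from riskupdate.errors import FitError
from riskupdate.logistic import FitMeta

from conftest import make_continuous_schema


def _prior(p, alpha=-1.0, betas=None):
    betas = np.full(p, 0.5) if betas is None else np.asarray(betas, dtype=float)
    return LogisticModel(alpha=alpha, betas=betas, fit_meta=FitMeta(converged=True))


def _updater(case_coef, case_sd, control_coef, control_sd, prior=None, variant="full"):
    p = len(case_coef) - 1
    return ClrUpdater(
        prior=prior or _prior(p),
        variant=variant,
        case_model=ConditionalMarkerModel(np.asarray(case_coef, float), case_sd),
        control_model=ConditionalMarkerModel(np.asarray(control_coef, float), control_sd),
    )


def _clr_dataset(prior, case, control, n, seed):
    """Draw (X, y, m) from a CLR-style truth with standard-normal predictors."""
    rng = np.random.default_rng(seed)
    p = prior.betas.shape[0]
    X = rng.standard_normal((n, p))
    prob = 1 / (1 + np.exp(-(prior.alpha + X @ prior.betas)))
    y = (rng.random(n) < prob).astype(int)
    mu = np.where(y == 1, case.mean(X), control.mean(X))
    sd = np.where(y == 1, case.residual_sd, control.residual_sd)
    m = mu + sd * rng.standard_normal(n)
    return Dataset(schema=make_continuous_schema(p), X=X, y=y, marker=m)


class TestLikelihoodRatio:
    def test_identical_models_give_lr_one(self):
        upd = _updater([0.5, 0.3], 1.2, [0.5, 0.3], 1.2)
        for m in (-2.0, 0.0, 3.7):
            assert likelihood_ratio(upd, np.array([0.8]), m) == pytest.approx(1.0)

    def test_unit_shift_shared_sigma(self):
        # mu_case = 1, mu_control = 0, sigma = 1, m = 1: LR = phi(0)/phi(1) = exp(1/2)
        upd = _updater([1.0, 0.0], 1.0, [0.0, 0.0], 1.0)
        lr = likelihood_ratio(upd, np.array([0.0]), 1.0)
        assert lr == pytest.approx(np.exp(0.5), rel=1e-12)

    def test_sd_ratio_at_shared_mean(self):
        upd = _updater([0.7, 0.2], 2.0, [0.7, 0.2], 0.5)
        row = np.array([1.3])
        m = 0.7 + 0.2 * 1.3
        assert likelihood_ratio(upd, row, m) == pytest.approx(0.5 / 2.0, rel=1e-12)

    def test_log_lr_antisymmetric_under_swap(self):
        upd = _updater([1.0, 0.4], 1.5, [-0.3, 0.1], 0.8)
        swapped = _updater([-0.3, 0.1], 0.8, [1.0, 0.4], 1.5)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 1))
        m = rng.standard_normal(20)
        lr = upd.log_likelihood_ratio(X, m)
        lr_swapped = swapped.log_likelihood_ratio(X, m)
        np.testing.assert_allclose(lr, -lr_swapped, atol=1e-12)

    def test_strictly_positive_finite_for_extreme_marker(self):
        upd = _updater([0.0, 0.0], 1.0, [1.0, 0.0], 2.0)
        lr = likelihood_ratio(upd, np.array([0.0]), 200.0)
        assert np.isfinite(lr) and lr > 0


class TestUpdatePrediction:
    def test_lr_one_returns_prior(self):
        upd = _updater([0.5, 0.2], 1.0, [0.5, 0.2], 1.0)
        row = np.array([1.0])
        prior_prob = 1 / (1 + np.exp(-(upd.prior.alpha + row @ upd.prior.betas)))
        assert update_prediction(upd, row, 0.3) == pytest.approx(prior_prob, rel=1e-12)

    def test_prior_odds_one_lr_two(self):
        # alpha chosen so lp0 = 0 at row 0; LR=2 at the case mean with sd ratio 2
        prior = _prior(1, alpha=0.0, betas=[0.0])
        upd = _updater([0.0, 0.0], 1.0, [0.0, 0.0], 2.0, prior=prior)
        post = update_prediction(upd, np.array([0.0]), 0.0)  # LR = 2/1 = 2 at mean
        assert post == pytest.approx(2 / 3, rel=1e-12)

    def test_posterior_increasing_in_lr(self):
        prior = _prior(1, alpha=-0.4, betas=[0.3])
        upd = _updater([1.0, 0.0], 1.0, [0.0, 0.0], 1.0, prior=prior)
        ms = np.linspace(-3, 3, 25)  # log LR increases linearly in m here
        posts = np.array([update_prediction(upd, np.array([0.5]), m) for m in ms])
        assert (np.diff(posts) > 0).all()

    def test_homoscedastic_closed_form(self):
        # shared sigma: posterior log-odds = lp0 + [(m-mu0)^2 - (m-mu1)^2] / (2 sigma^2)
        sigma = 1.3
        prior = _prior(2, alpha=-0.8, betas=[0.6, -0.2])
        upd = _updater([1.1, 0.5, -0.3], sigma, [0.2, 0.4, 0.1], sigma, prior=prior)
        rng = np.random.default_rng(11)
        for _ in range(50):
            row = rng.standard_normal(2)
            m = rng.normal(0, 2)
            lp0 = prior.alpha + row @ prior.betas
            mu1 = upd.case_model.mean(row)[0]
            mu0 = upd.control_model.mean(row)[0]
            expected = lp0 + ((m - mu0) ** 2 - (m - mu1) ** 2) / (2 * sigma**2)
            post = update_prediction(upd, row, m)
            assert np.log(post / (1 - post)) == pytest.approx(expected, abs=1e-10)


class TestFitClr:
    def test_parameter_storage_full(self):
        prior = _prior(3)
        case = ConditionalMarkerModel(np.zeros(4), 1.0)
        control = ConditionalMarkerModel(np.ones(4), 2.0)
        upd = ClrUpdater(prior=prior, variant="full", case_model=case, control_model=control)
        # 2(p+1) mean coefficients + 2 residual SDs at p = 3 -> 10 parameters
        assert upd.n_parameters == 10

    def test_parameter_storage_simple(self):
        prior = _prior(3)
        shared = np.array([0.5, 0.1, 0.2, 0.3])
        case = shared.copy()
        case[0] += 1.0
        upd = ClrUpdater(
            prior=prior, variant="simple",
            case_model=ConditionalMarkerModel(case, 1.1),
            control_model=ConditionalMarkerModel(shared, 1.1),
        )
        assert upd.n_parameters == 6

    def test_recovery_of_generating_models(self):
        prior = _prior(2, alpha=0.0, betas=[0.8, -0.5])
        case = ConditionalMarkerModel(np.array([1.5, 0.7, -0.2]), 1.4)
        control = ConditionalMarkerModel(np.array([0.3, 0.5, 0.1]), 0.9)
        data = _clr_dataset(prior, case, control, 40_000, seed=77)
        upd = fit_clr(prior, data)
        for fitted, truth in ((upd.case_model, case), (upd.control_model, control)):
            n_g = int((data.y == (1 if truth is case else 0)).sum())
            se_coef = truth.residual_sd / np.sqrt(n_g)  # conservative MC scale
            np.testing.assert_array_less(np.abs(fitted.coef - truth.coef), 3 * se_coef * 3)
            se_sd = truth.residual_sd / np.sqrt(2 * n_g)
            assert abs(fitted.residual_sd - truth.residual_sd) < 3 * se_sd

    def test_zero_residual_variance_is_an_error(self):
        prior = _prior(1)
        rng = np.random.default_rng(8)
        X = rng.standard_normal((60, 1))
        y = np.tile([0, 1], 30)
        data = Dataset(schema=make_continuous_schema(1), X=X, y=y, marker=X[:, 0].copy())
        with pytest.raises(FitError):
            fit_clr(prior, data)

    def test_too_small_group_names_the_group(self):
        prior = _prior(2)
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10, 2))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])  # 1 event < p + 2
        data = Dataset(schema=make_continuous_schema(2), X=X, y=y,
                       marker=rng.standard_normal(10))
        with pytest.raises(FitError, match="event group"):
            fit_clr(prior, data)


class TestFitClrSimple:
    def test_shared_slopes_and_sd(self):
        prior = _prior(2)
        case = ConditionalMarkerModel(np.array([1.0, 0.5, -0.2]), 1.0)
        control = ConditionalMarkerModel(np.array([0.0, 0.5, -0.2]), 1.0)
        data = _clr_dataset(prior, case, control, 5_000, seed=88)
        upd = fit_clr_simple(prior, data)
        assert upd.variant == "simple"
        np.testing.assert_array_equal(upd.case_model.coef[1:], upd.control_model.coef[1:])
        assert upd.case_model.residual_sd == upd.control_model.residual_sd

    def test_equal_shift_truth_makes_variants_agree(self):
        # homoscedastic equal-slope groups: full and simple estimate the same LR
        prior = _prior(2, alpha=-0.5, betas=[0.6, -0.4])
        case = ConditionalMarkerModel(np.array([1.2, 0.5, -0.2]), 1.1)
        control = ConditionalMarkerModel(np.array([0.2, 0.5, -0.2]), 1.1)
        data = _clr_dataset(prior, case, control, 50_000, seed=89)
        full = fit_clr(prior, data)
        simple = fit_clr_simple(prior, data)
        grid = data.subset(np.arange(300))
        lr_full = np.exp(full.log_likelihood_ratio(grid.X, grid.marker))
        lr_simple = np.exp(simple.log_likelihood_ratio(grid.X, grid.marker))
        np.testing.assert_allclose(lr_full, lr_simple, rtol=0.12)

    def test_null_indicator_gives_lr_near_one(self):
        prior = _prior(1, alpha=-0.3, betas=[0.5])
        shared = ConditionalMarkerModel(np.array([0.4, 0.6]), 1.0)
        data = _clr_dataset(prior, shared, shared, 50_000, seed=90)
        upd = fit_clr_simple(prior, data)
        lr = np.exp(upd.log_likelihood_ratio(data.X[:500], data.marker[:500]))
        assert np.abs(np.log(lr)).max() < 0.15

    def test_indicator_coefficient_recovers_shift(self):
        prior = _prior(1, alpha=0.0, betas=[0.4])
        case = ConditionalMarkerModel(np.array([1.0, 0.5]), 1.0)
        control = ConditionalMarkerModel(np.array([0.0, 0.5]), 1.0)
        data = _clr_dataset(prior, case, control, 30_000, seed=91)
        upd = fit_clr_simple(prior, data)
        assert upd.indicator_coefficient == pytest.approx(1.0, abs=0.05)


class TestClrInvariants:
    def test_updater_never_touches_prior_coefficients(self):
        prior = _prior(2, alpha=-0.7, betas=[0.6, -0.1])
        alpha0, betas0 = prior.alpha, prior.betas.copy()
        case = ConditionalMarkerModel(np.array([1.0, 0.3, 0.2]), 1.2)
        control = ConditionalMarkerModel(np.array([0.0, 0.3, 0.2]), 1.0)
        data = _clr_dataset(prior, case, control, 2_000, seed=92)
        upd = fit_clr(prior, data)
        upd.linear_predictor(data)
        assert upd.prior.alpha == alpha0
        np.testing.assert_array_equal(upd.prior.betas, betas0)

    def test_posterior_converges_to_truth_with_n(self):
        prior = _prior(2, alpha=-0.8, betas=[0.7, -0.3])
        case = ConditionalMarkerModel(np.array([1.3, 0.4, -0.2]), 1.3)
        control = ConditionalMarkerModel(np.array([0.2, 0.3, 0.1]), 0.9)
        truth = ClrUpdater(prior=prior, variant="full", case_model=case,
                           control_model=control)
        probe = _clr_dataset(prior, case, control, 2_000, seed=93)
        true_post = truth.predict_probability(probe)
        errs = []
        for n in (500, 5_000, 50_000):
            data = _clr_dataset(prior, case, control, n, seed=94)
            fitted = fit_clr(prior, data)
            errs.append(np.abs(fitted.predict_probability(probe) - true_post).mean())
        assert errs[2] < errs[0]
        assert errs[2] < 0.01
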