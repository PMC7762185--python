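import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbemap import compare_fits, dose_at_sf, fit_lq_poisson, predict_sf
from rbemap.lq_model import LQFitError, _poisson_nll_and_grad

DOSES5 = np.array([0.0, 1.0, 2.0, 4.0, 6.0])


def _mk(alpha, beta):
    from rbemap import LQFit

    return LQFit(
        alpha=alpha, beta=beta, covariance=np.zeros((2, 2)), pe=0.5,
        cells_seeded=100, log_likelihood=0.0, deviance=0.0, n_points=0,
    )


def _grid_oracle(doses, counts, offset, alpha_max=1.5, beta_max=0.15, n=400):
    """Dense grid search maximizing the same Poisson likelihood."""
    alphas = np.linspace(0.0, alpha_max, n)
    betas = np.linspace(0.0, beta_max, n)
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    nll = np.zeros_like(A)
    for d, c in zip(doses, counts):
        log_mu = math.log(offset) - A * d - B * d * d
        nll += np.exp(log_mu) - c * log_mu
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    return alphas[i], betas[j], alphas[1] - alphas[0], betas[1] - betas[0]


def _expected_counts(alpha, beta, doses, offset):
    return offset * np.exp(-alpha * doses - beta * doses**2)


class TestFit:
    def test_noiseless_counts_recover_truth_and_match_grid(self):
        alpha, beta, offset = 0.5, 0.05, 50.0
        counts = _expected_counts(alpha, beta, DOSES5, offset)
        fit = fit_lq_poisson(DOSES5, counts, cells_seeded=100, pe=0.5)
        assert fit.alpha == pytest.approx(alpha, abs=1e-4)
        assert fit.beta == pytest.approx(beta, abs=1e-4)
        ga, gb, da, db = _grid_oracle(DOSES5, counts, offset)
        assert abs(fit.alpha - ga) <= da
        assert abs(fit.beta - gb) <= db

    def test_single_dose_pure_alpha_closed_form(self):
        # exact counts for SF = e^-1 at 2 Gy with beta fixed to 0
        counts = np.full(8, 50.0 * math.exp(-1.0))
        doses = np.full(8, 2.0)
        fit = fit_lq_poisson(doses, counts, 100, 0.5, fix_beta_zero=True)
        assert fit.alpha == pytest.approx(0.5, abs=1e-8)
        assert fit.beta == 0.0
        assert fit.beta_at_boundary

    def test_pure_alpha_truth_pins_beta_at_boundary(self):
        # mirrors the pure-alpha fit seen at the highest beam quality
        rng = np.random.default_rng(7)
        pinned = 0
        for _ in range(100):
            counts = rng.poisson(_expected_counts(1.2, 0.0, DOSES5, 50.0), size=(16, 5))
            fit = fit_lq_poisson(
                np.tile(DOSES5, 16), counts.ravel(), 100, 0.5
            )
            pinned += fit.beta_at_boundary
        assert pinned > 50

    def test_matches_statsmodels_glm_on_interior_instance(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        doses = np.tile(DOSES5, 16)
        counts = rng.poisson(_expected_counts(0.4, 0.06, doses, 50.0))
        fit = fit_lq_poisson(doses, counts, 100, 0.5)
        X = np.column_stack([-doses, -(doses**2)])
        glm = sm.GLM(
            counts,
            X,
            family=sm.families.Poisson(),
            offset=np.full(doses.size, math.log(50.0)),
        ).fit()
        assert fit.alpha == pytest.approx(glm.params[0], rel=1e-5)
        assert fit.beta == pytest.approx(glm.params[1], rel=1e-4)
        cov = glm.cov_params()
        assert fit.covariance[0, 0] == pytest.approx(cov[0, 0], rel=2e-2)
        assert fit.covariance[1, 1] == pytest.approx(cov[1, 1], rel=2e-2)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(LQFitError, match="zero"):
            fit_lq_poisson(DOSES5, np.zeros(5), 100, 0.5)

    def test_wald_intervals_cover_true_alpha(self):
        # 200 simulations at the assay design: 5 dose levels, 16 wells each,
        # 100 cells/well, PE 0.5; 95% Wald coverage of alpha in [0.90, 0.99]
        rng = np.random.default_rng(20260924)
        alpha, beta = 0.5, 0.05
        doses = np.tile(DOSES5, 16)
        mu = _expected_counts(alpha, beta, doses, 50.0)
        covered = 0
        n_sim = 200
        for _ in range(n_sim):
            fit = fit_lq_poisson(doses, rng.poisson(mu), 100, 0.5)
            se = math.sqrt(fit.covariance[0, 0])
            covered += abs(fit.alpha - alpha) <= 1.96 * se
        assert 0.90 * n_sim <= covered <= 0.99 * n_sim


class TestCurve:
    def test_predict_sf_identity_at_zero_dose(self, make_fit):
        assert predict_sf(make_fit(0.7, 0.03), 0.0) == 1.0

    def test_predict_sf_closed_form(self, make_fit):
        assert predict_sf(make_fit(0.5, 0.0), 2.0) == pytest.approx(math.exp(-1))

    def test_negative_dose_rejected(self, make_fit):
        with pytest.raises(ValueError):
            predict_sf(make_fit(0.5, 0.0), -1.0)

    @pytest.mark.parametrize(
        "alpha, beta, sf, expected",
        [(0.5, 0.0, math.exp(-1), 2.0), (0.0, 0.25, math.exp(-1), 2.0)],
    )
    def test_dose_at_sf_limits(self, make_fit, alpha, beta, sf, expected):
        assert dose_at_sf(make_fit(alpha, beta), sf) == pytest.approx(expected)

    def test_dose_at_sf_matches_bisection_oracle(self, make_fit):
        from scipy.optimize import brentq

        fit = make_fit(0.5, 0.05)
        oracle = brentq(lambda d: predict_sf(fit, d) - 0.1, 1e-9, 100.0, xtol=1e-12)
        d = dose_at_sf(fit, 0.1)
        assert d == pytest.approx(oracle, abs=1e-9)
        assert d == pytest.approx(3.4292, abs=1e-3)
        assert predict_sf(fit, d) == pytest.approx(0.1, abs=1e-3)

    def test_flat_curve_has_no_isosurvival_dose(self, make_fit):
        with pytest.raises(LQFitError, match="flat"):
            dose_at_sf(make_fit(0.0, 0.0), 0.5)

    @given(
        alpha=st.one_of(st.just(0.0), st.floats(1e-3, 3.0)),
        beta=st.one_of(st.just(0.0), st.floats(1e-4, 0.3)),
        sf=st.sampled_from([0.9, 0.5, 0.1, 0.01]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_inverse_consistency(self, alpha, beta, sf):
        if alpha == 0 and beta == 0:
            alpha = 0.1
        fit = _mk(alpha, beta)
        assert predict_sf(fit, dose_at_sf(fit, sf)) == pytest.approx(sf, abs=1e-9)

    @given(
        alpha=st.floats(0.01, 3.0),
        beta=st.floats(0.0, 0.3),
        d1=st.floats(0.0, 10.0),
        step=st.floats(0.01, 5.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_sf_strictly_decreasing_in_dose(self, alpha, beta, d1, step):
        fit = _mk(alpha, beta)
        assert predict_sf(fit, d1 + step) < predict_sf(fit, d1)


class TestCompareFits:
    @staticmethod
    def _dataset(alpha, beta, rng):
        doses = np.tile(DOSES5, 16)
        counts = rng.poisson(_expected_counts(alpha, beta, doses, 50.0))
        return (doses, counts, 100, 0.5)

    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(3)
        ds = self._dataset(0.5, 0.05, rng)
        cmp = compare_fits(ds, ds)
        assert cmp.statistic == pytest.approx(0.0, abs=1e-6)
        assert cmp.p_value == pytest.approx(1.0, abs=1e-6)

    def test_null_rarely_rejects(self):
        rng = np.random.default_rng(5)
        n_reject = sum(
            compare_fits(self._dataset(0.5, 0.05, rng), self._dataset(0.5, 0.05, rng)).p_value
            < 0.05
            for _ in range(100)
        )
        assert n_reject <= 10

    def test_strong_alternative_usually_rejects(self):
        rng = np.random.default_rng(6)
        n_reject = sum(
            compare_fits(self._dataset(0.5, 0.05, rng), self._dataset(1.0, 0.05, rng)).p_value
            < 0.05
            for _ in range(100)
        )
        assert n_reject >= 90

    def test_degrees_of_freedom_accounting(self):
        rng = np.random.default_rng(8)
        cmp = compare_fits(self._dataset(0.5, 0.05, rng), self._dataset(0.5, 0.05, rng))
        assert cmp.df_num >= 1
        assert cmp.df_den == 160 - 4


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(2)
    doses = np.tile(DOSES5, 4)
    counts = rng.poisson(_expected_counts(0.6, 0.04, doses, 50.0)).astype(float)
    offsets = np.full(doses.size, 50.0)
    theta = np.array([0.45, 0.03])
    _, grad = _poisson_nll_and_grad(theta, doses, counts, offsets)
    eps = 1e-6
    for k in range(2):
        dt = np.zeros(2)
        dt[k] = eps
        up, _ = _poisson_nll_and_grad(theta + dt, doses, counts, offsets)
        dn, _ = _poisson_nll_and_grad(theta - dt, doses, counts, offsets)
        assert grad[k] == pytest.approx((up - dn) / (2 * eps), rel=1e-5)
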