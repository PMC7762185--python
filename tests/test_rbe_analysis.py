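import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbemap import (
    analyze_experiment,
    build_profile,
    compute_rbe,
    detect_overkill,
    dose_at_sf,
    load_fixture,
    profile_from_table,
    rbe_se_delta,
)
from rbemap.rbe_analysis import RBEProfile, ProfilePoint, RBEEstimate


def _mk(alpha, beta):
    from rbemap import LQFit

    return LQFit(
        alpha=alpha, beta=beta, covariance=np.zeros((2, 2)), pe=0.5,
        cells_seeded=100, log_likelihood=0.0, deviance=0.0, n_points=0,
    )


def _profile_from_values(values, sf_level=0.5):
    """Profile with given rbe values at columns 1..n, y_d = 10*column."""
    points = []
    for i, v in enumerate(values):
        est = (
            RBEEstimate(sf_level=sf_level, rbe=None, se=None, excluded=True, reason="x")
            if v is None
            else RBEEstimate(sf_level=sf_level, rbe=v, se=None)
        )
        points.append(
            ProfilePoint(column_index=i + 1, y_d=10.0 * (i + 1), estimates={sf_level: est})
        )
    return RBEProfile(points=points, sf_levels=(sf_level,))


class TestComputeRBE:
    def test_identical_curves_give_unity(self, make_fit):
        f = make_fit(0.5, 0.05)
        for s in (0.9, 0.5, 0.1, 0.01):
            assert compute_rbe(f, f, s).rbe == pytest.approx(1.0)

    @given(
        k=st.floats(0.2, 5.0),
        alpha=st.floats(0.05, 1.0),
        beta=st.floats(0.0, 0.1),
        sf=st.floats(0.01, 0.95),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scaling_identity(self, k, alpha, beta, sf):
        # ion (k*alpha, k^2*beta) vs reference (alpha, beta) => RBE = k exactly
        ref = _mk(alpha, beta)
        ion = _mk(k * alpha, k * k * beta)
        assert compute_rbe(ref, ion, sf).rbe == pytest.approx(k, rel=1e-10)

    def test_dose_ratio_against_bisection_oracle(self, make_fit):
        from scipy.optimize import brentq

        ref, ion = make_fit(0.5, 0.05), make_fit(1.0, 0.1)
        d_ref = brentq(lambda d: math.exp(-0.5 * d - 0.05 * d * d) - 0.1, 1e-9, 100)
        d_ion = brentq(lambda d: math.exp(-1.0 * d - 0.1 * d * d) - 0.1, 1e-9, 100)
        est = compute_rbe(ref, ion, 0.1)
        assert est.rbe == pytest.approx(d_ref / d_ion, rel=1e-9)
        assert est.rbe == pytest.approx(1.777, abs=2e-3)

    def test_dose_unit_relabelling_invariance(self, make_fit):
        # scaling dose units by c maps (alpha, beta) -> (alpha/c, beta/c^2)
        # on both fits and leaves RBE unchanged
        c = 100.0  # Gy -> cGy
        ref, ion = make_fit(0.3, 0.03), make_fit(0.9, 0.05)
        ref_c, ion_c = make_fit(0.3 / c, 0.03 / c**2), make_fit(0.9 / c, 0.05 / c**2)
        for s in (0.5, 0.1):
            assert compute_rbe(ref, ion, s).rbe == pytest.approx(
                compute_rbe(ref_c, ion_c, s).rbe, rel=1e-12
            )

    def test_coverage_exclusion_mirrors_table_flags(self, make_fit):
        ref = make_fit(0.2, 0.02)
        ion = make_fit(0.4, 0.0, max_dose_covered=1.0)
        # isosurvival dose at SF 0.1 is 5.76 Gy >> 1 Gy of coverage
        est = compute_rbe(ref, ion, 0.1)
        assert est.excluded and est.rbe is None
        assert "coverage" in est.reason
        # SF 0.8 needs only 0.56 Gy: inside coverage
        assert not compute_rbe(ref, ion, 0.8).excluded


class TestDeltaMethodSE:
    def test_zero_covariances_give_zero_se(self, make_fit):
        assert rbe_se_delta(make_fit(0.2, 0.02), make_fit(0.5, 0.05), 0.5) == 0.0

    def test_gradient_matches_finite_differences(self, make_fit):
        rng = np.random.default_rng(4)
        from rbemap.rbe_analysis import _isodose_gradient

        for _ in range(25):
            alpha = rng.uniform(0.05, 1.5)
            beta = rng.uniform(0.005, 0.15)
            sf = rng.uniform(0.02, 0.9)
            fit = make_fit(alpha, beta)
            _, grad = _isodose_gradient(fit, sf)
            eps = 1e-7
            for k, (da, db) in enumerate([(eps, 0.0), (0.0, eps)]):
                up = dose_at_sf(make_fit(alpha + da, beta + db), sf)
                dn = dose_at_sf(make_fit(alpha - da, beta - db), sf)
                assert grad[k] == pytest.approx((up - dn) / (2 * eps), rel=1e-6)

    def test_matches_parametric_bootstrap(self, make_fit):
        # SD of RBE under resampled (alpha, beta) agrees with the delta
        # method within 10% at small covariance scale
        rng = np.random.default_rng(9)
        cov_ion = np.array([[4e-4, -6e-6], [-6e-6, 4e-7]])
        cov_ref = np.array([[1e-4, -2e-6], [-2e-6, 1e-7]])
        ref = make_fit(0.2, 0.02, cov=cov_ref)
        ion = make_fit(0.8, 0.06, cov=cov_ion)
        se = rbe_se_delta(ref, ion, 0.1)
        n = 10_000
        L = -math.log(0.1)

        def iso(a, b):
            return 2 * L / (a + np.sqrt(a * a + 4 * b * L))

        a_r, b_r = rng.multivariate_normal([0.2, 0.02], cov_ref, size=n).T
        a_i, b_i = rng.multivariate_normal([0.8, 0.06], cov_ion, size=n).T
        rbes = iso(a_r, b_r) / iso(a_i, b_i)
        assert se == pytest.approx(rbes.std(), rel=0.10)

    def test_boundary_pinned_parameter_makes_se_unavailable(self, make_fit):
        cov = np.array([[1e-4, np.nan], [np.nan, np.nan]])
        ion = make_fit(0.5, 0.0, cov=cov, beta_at_boundary=True)
        ref = make_fit(0.2, 0.02)
        est = compute_rbe(ref, ion, 0.5)
        assert est.se is None and est.rbe is not None


class TestProfiles:
    def test_table_profile_reproduces_published_peaks(self):
        he = profile_from_table(load_fixture("H460", "helium"))
        assert he.peak(0.5) == (88.0, 4.10, 11)
        assert he.peak(0.1) == (84.9, 4.25, 10)
        ca = profile_from_table(load_fixture("H460", "carbon"))
        assert ca.peak(0.5) == (87.9, 5.24, 6)
        assert ca.minimum(0.5) == (270.3, 0.68, 12)
        assert detect_overkill(ca, 0.5) is True

    def test_monotone_rise_is_not_overkill(self):
        assert detect_overkill(_profile_from_values([1, 2, 3, 4]), 0.5) is False

    def test_rise_then_fall_is_overkill(self):
        assert detect_overkill(_profile_from_values([1, 2, 5, 3, 2]), 0.5) is True

    def test_flat_profile_is_not_overkill(self):
        assert detect_overkill(_profile_from_values([2, 2, 2, 2]), 0.5) is False

    def test_too_few_points_is_undefined_not_false(self):
        assert detect_overkill(_profile_from_values([1, 2]), 0.5) is None
        assert detect_overkill(_profile_from_values([1, 2, None, None]), 0.5) is None

    def test_excluded_points_skipped_in_peak_search(self):
        prof = _profile_from_values([1.0, None, 3.0, 2.0])
        assert prof.peak(0.5) == (30.0, 3.0, 3)

    def test_fewer_than_two_points_has_no_peak(self):
        assert _profile_from_values([1.0, None, None]).peak(0.5) is None

    def test_build_profile_requires_y_d(self, make_fit, photon_reference):
        from rbemap.rbe_analysis import RBEError

        with pytest.raises(RBEError, match="y_d"):
            build_profile([make_fit(0.5, 0.05)], photon_reference)

    def test_peak_tie_breaks_toward_lower_y_d(self):
        prof = _profile_from_values([1.0, 4.0, 4.0, 2.0])
        assert prof.peak(0.5) == (20.0, 4.0, 2)


class TestEndToEnd:
    def test_pipeline_recovers_truth_peak_column(
        self, carbon_experiment, photon_reference
    ):
        experiment, truth = carbon_experiment
        profile = analyze_experiment(experiment, photon_reference)
        peak = profile.peak(0.5)
        assert peak[2] == 6  # truth alpha peaks at y_d 87.9 (column 6)
        assert peak[1] == pytest.approx(truth.rbe(87.9, 0.5), rel=0.15)
        assert detect_overkill(profile, 0.5) is True

    def test_proton_like_monotone_profile_shows_no_overkill(
        self, make_fit, photon_reference
    ):
        fits = [
            make_fit(0.2 * (1 + 0.1 * i), 0.02, y_d=float(i + 1), column_index=i + 1)
            for i in range(6)
        ]
        profile = build_profile(fits, photon_reference, sf_levels=(0.1,))
        assert detect_overkill(profile, 0.1) is False
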