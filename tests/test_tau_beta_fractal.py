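"""The tau-beta diagram, the Ryabov relation, and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hydrofractal as hf
from hydrofractal import SelfDiffusionScaling, TauBetaPoint
from hydrofractal.relaxation_models import DomainError, ParameterError
from hydrofractal.tau_beta_fractal import TAU0_SCALING_DEFAULT


class TestRyabovRelation:
    def test_hand_computed_value(self):
        # D=1, omega_s=1e11, tau0=1 ps, tau=100 ps: 0.5*ln(10)/ln(100)
        beta = hf.ryabov_beta(1e-10, 1.0, 1e11, 1e-12)
        assert beta == pytest.approx(0.5 * np.log(10) / np.log(100), rel=1e-12)
        assert beta == pytest.approx(0.25)

    def test_zero_crossing_at_inverse_omega_s(self):
        # dyadic omega_s so that tau * omega_s is exactly 1.0 in floats
        omega_s = float(2**40)
        tau = 2.0**-40
        for D, tau0 in [(0.5, 1e-13), (1.8, 3e-12)]:
            assert hf.ryabov_beta(tau, D, omega_s, tau0) == 0.0

    def test_asymptote_is_half_d(self):
        # with tau0 * omega_s of order one, beta is within 1% of D/2
        # already at tau = 1e6 tau0, and converges further beyond
        tau0 = 1e-12
        omega_s = 1.1 / tau0
        dev6 = abs(hf.ryabov_beta(1e6 * tau0, 1.8, omega_s, tau0) - 0.9)
        dev9 = abs(hf.ryabov_beta(1e9 * tau0, 1.8, omega_s, tau0) - 0.9)
        assert dev6 / 0.9 < 0.01
        assert dev9 < dev6

    def test_singularity_and_domain_errors(self):
        with pytest.raises(DomainError):
            hf.ryabov_beta(1e-12, 1.0, 1e11, 1e-12)
        with pytest.raises(DomainError):
            hf.ryabov_beta(-1e-12, 1.0, 1e11, 1e-12)
        with pytest.raises(DomainError):
            hf.ryabov_beta(1e-10, 1.0, -1e11, 1e-12)


class TestOmegaSPhysical:
    def test_unit_inputs(self):
        s = SelfDiffusionScaling(d_E=3, D_s=1.0, R0=1.0, G=1.0)
        assert hf.omega_s_physical(s, 0.7) == pytest.approx(6.0)

    def test_hand_arithmetic(self):
        s = SelfDiffusionScaling(d_E=1, D_s=1.0, R0=1.0, G=2.0)
        assert hf.omega_s_physical(s, 2.0) == pytest.approx(4.0)

    def test_inverse_square_in_cutoff_size(self):
        s1 = SelfDiffusionScaling(d_E=3, D_s=2e-9, R0=1e-9)
        s2 = SelfDiffusionScaling(d_E=3, D_s=2e-9, R0=2e-9)
        assert hf.omega_s_physical(s1, 1.5) == pytest.approx(4 * hf.omega_s_physical(s2, 1.5))

    def test_invalid(self):
        with pytest.raises(ParameterError):
            SelfDiffusionScaling(d_E=4, D_s=1.0, R0=1.0)
        with pytest.raises(DomainError):
            hf.omega_s_physical(SelfDiffusionScaling(d_E=3, D_s=1.0, R0=1.0), 0.0)


class TestTrajectoryFit:
    def test_noise_free_roundtrip(self):
        pts = hf.make_trajectory(1.44, n_points=10)
        fit = hf.fit_trajectory(pts)
        assert fit.D == pytest.approx(1.44, abs=0.05)
        assert fit.converged

    def test_fitted_curve_asymptote_equals_half_d(self):
        """The horizontal asymptote of the fitted hyperbola is D/2."""
        pts = hf.make_trajectory(1.2, n_points=10)
        fit = hf.fit_trajectory(pts)
        beta_far = hf.ryabov_beta(1e250 * fit.tau0_s, fit.D, fit.omega_s, fit.tau0_s)
        assert abs(beta_far - fit.D / 2) / (fit.D / 2) < 0.01

    def test_too_few_or_degenerate_points(self):
        pts = hf.make_trajectory(1.0, n_points=4)
        with pytest.raises(DomainError):
            hf.fit_trajectory(pts[:3])
        same = [TauBetaPoint(tau=1e-11, beta=b) for b in (0.9, 0.8, 0.7, 0.6)]
        with pytest.raises(DomainError):
            hf.fit_trajectory(same)

    def test_dispersion_uncertainty_much_larger_than_solution(self):
        """Dispersion-type arcs are nearly vertical, so the horizontal
        asymptote (hence D) is an extrapolation with a much larger error
        than for solution-type arcs at the same beta noise."""
        rng = np.random.default_rng(5)
        u_disp, u_sol = [], []
        for _ in range(30):
            fit = hf.fit_trajectory(hf.make_trajectory(0.16, 12, noise=0.02, rng=rng))
            u_disp.append(fit.D_uncertainty)
            fit = hf.fit_trajectory(hf.make_trajectory(1.44, 12, noise=0.02, rng=rng))
            u_sol.append(fit.D_uncertainty)
        assert np.median(u_disp) > 2.0 * np.median(u_sol)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.3, max_value=1.7))
    def test_noise_free_recovery_property(self, D):
        fit = hf.fit_trajectory(hf.make_trajectory(D, n_points=10))
        assert abs(fit.D - D) < 0.05

    def test_generator_hits_pure_water_anchor(self):
        """Every generated trajectory starts at (8.3 ps, beta=1)."""
        for D in (0.3, 0.9, 1.5):
            L = np.log(2) * (2 / D - 1)
            omega_s = np.exp(L) / TAU0_SCALING_DEFAULT
            beta_at_anchor = hf.ryabov_beta(2 * TAU0_SCALING_DEFAULT, D, omega_s, TAU0_SCALING_DEFAULT)
            assert beta_at_anchor == pytest.approx(1.0, rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "D,u,expected",
        [
            (1.74, 0.04, "solution"),
            (0.16, 0.05, "dispersion"),
            (0.16, 1.49, "indeterminate"),
            (1.0, 0.0, "indeterminate"),
            (1.05, 0.40, "indeterminate"),
        ],
    )
    def test_interval_based_classes(self, D, u, expected):
        assert hf.classify_water_structure(D, u) == expected

    def test_negative_d_rejected(self):
        with pytest.raises(DomainError):
            hf.classify_water_structure(-0.1, 0.0)

    def test_classification_after_fitting_solution_arc(self):
        rng = np.random.default_rng(3)
        pts = hf.make_trajectory(1.5, 12, noise=0.01, rng=rng)
        fit = hf.fit_trajectory(pts)
        assert hf.classify_water_structure(fit.D, fit.D_uncertainty) == "solution"


class TestBulkNormalization:
    @staticmethod
    def _points(taus, comps, beta=0.8):
        return [
            TauBetaPoint(tau=t, beta=beta, composition=c, label=f"c={c}")
            for t, c in zip(taus, comps)
        ]

    def test_identity(self):
        comps = [0.1, 0.3, 0.5, 0.8]
        taus = [1e-11, 2e-11, 3e-11, 4e-11]
        res = hf.normalize_by_bulk(self._points(taus, comps), self._points(taus, comps))
        assert not res.errors
        assert all(p.tau_normalized == pytest.approx(1.0) for p in res.points)

    def test_constant_ratio(self):
        comps = [0.1, 0.3, 0.5, 0.8]
        taus = np.array([1e-11, 2e-11, 3e-11, 4e-11])
        res = hf.normalize_by_bulk(
            self._points(2 * taus, comps), self._points(taus, comps)
        )
        assert all(p.tau_normalized == pytest.approx(2.0) for p in res.points)

    def test_reentrant_bulk_straightens(self):
        """A non-monotone (reentrant) bulk tau trend divides out, leaving
        a monotone normalized trajectory for the matching gel series."""
        comps = np.linspace(0.0, 1.0, 9)
        bulk_tau = 1e-11 * (1 + 2.0 * np.sin(np.pi * comps))  # reentrant
        gel_tau = bulk_tau * (1 + 3.0 * comps)  # restriction grows with c
        res = hf.normalize_by_bulk(
            self._points(gel_tau, comps), self._points(bulk_tau, comps)
        )
        norm = [p.tau_normalized for p in res.points]
        assert np.all(np.diff(norm) > 0)

    def test_out_of_range_composition_recorded_not_extrapolated(self):
        res = hf.normalize_by_bulk(
            self._points([1e-11], [0.9]), self._points([1e-11, 2e-11, 1e-11, 3e-11], [0.1, 0.3, 0.5, 0.7])
        )
        assert len(res.points) == 0
        assert len(res.errors) == 1 and "outside bulk range" in res.errors[0]

    def test_point_invariants(self):
        with pytest.raises(ParameterError):
            TauBetaPoint(tau=1e-11, beta=1.2)
        with pytest.raises(ParameterError):
            TauBetaPoint(tau=-1e-11, beta=0.5)
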