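import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from memti.constants import MU0
from memti.magnetostriction import (
    bias_sweep,
    effective_field,
    langevin,
    magnetization_of_field,
    me_strain,
    self_consistent_state,
    solve_axial_magnetization,
)


class TestLangevin:
    def test_zero(self):
        assert langevin(0.0) == 0.0

    def test_reference_value(self):
        # high-precision evaluation of coth(3) - 1/3
        assert langevin(3.0) == pytest.approx(0.671636489980357, abs=1e-5)

    def test_saturation_limit(self):
        # coth(50) - 1 is ~1e-43, so L(50) = 1 - 1/50 to double precision
        assert langevin(50.0) == pytest.approx(1.0 - 1.0 / 50.0, abs=1e-12)
        assert langevin(1e4) == pytest.approx(1.0 - 1e-4, abs=1e-12)
        assert langevin(1e4) < 1.0

    @given(st.floats(-500, 500, allow_nan=False))
    def test_odd_and_bounded(self, x):
        assert langevin(-x) == pytest.approx(-langevin(x), abs=1e-14)
        assert abs(langevin(x)) < 1.0

    def test_monotone_increasing(self):
        x = np.linspace(-30, 30, 2001)
        assert np.all(np.diff(langevin(x)) > 0)

    def test_series_matches_direct_form(self):
        # inside the series window the series must agree with the exact form
        x = 5e-5
        exact = 1.0 / np.tanh(x) - 1.0 / x
        assert langevin(x) == pytest.approx(exact, rel=1e-6)


class TestMagnetizationOfField:
    def test_zero_field(self, metglas):
        assert np.array_equal(magnetization_of_field(np.zeros(3), metglas), np.zeros(3))

    def test_saturates_at_ms(self, metglas):
        m = magnetization_of_field(np.array([0, 0, 1e9]), metglas)
        assert np.linalg.norm(m) == pytest.approx(700282.0, rel=1e-4)
        assert np.linalg.norm(m) < metglas.saturation_magnetization

    def test_initial_slope_is_chi0(self, metglas):
        h = np.array([0, 0, 1.0])
        m = magnetization_of_field(h, metglas)
        assert m[2] / h[2] == pytest.approx(200.0, rel=0.01)

    def test_direction_follows_field(self, metglas):
        h = np.array([3.0, -4.0, 12.0])
        m = magnetization_of_field(h, metglas)
        assert np.allclose(np.cross(m, h), 0.0, atol=1e-6)


class TestMeStrain:
    def test_zero_magnetization(self, metglas):
        assert np.array_equal(me_strain(np.zeros(3), metglas), np.zeros(6))

    def test_saturated_axial_strain(self, metglas):
        m = np.array([0, 0, metglas.saturation_magnetization])
        eps = me_strain(m, metglas)
        assert eps[2] == pytest.approx(12e-6, rel=1e-12)
        assert eps[0] == eps[1] == pytest.approx(-6e-6, rel=1e-12)

    @given(st.lists(st.floats(-7e5, 7e5), min_size=3, max_size=3))
    def test_traceless_and_even_in_m(self, metglas, mvec):
        m = np.asarray(mvec)
        eps = me_strain(m, metglas)
        assert abs(eps[:3].sum()) < 1e-12
        assert np.allclose(me_strain(-m, metglas), eps)


class TestEffectiveField:
    def test_zero_stress_identity(self, metglas):
        h = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(effective_field(h, np.zeros(6), np.ones(3), metglas), h)

    def test_zero_magnetization_identity(self, metglas):
        h = np.array([1.0, 2.0, 3.0])
        s = np.array([1e6, 0, 0, 0, 0, 0])
        assert np.array_equal(effective_field(h, s, np.zeros(3), metglas), h)

    def test_uniaxial_stress_shift(self, metglas):
        # independent scalar arithmetic: dH_z = 3 λs σ_zz M_z / (μ0 Ms²)
        ms = metglas.saturation_magnetization
        s = np.array([0, 0, 10e6, 0, 0, 0])
        m = np.array([0, 0, ms])
        expected = 3.0 * 12e-6 * 10e6 * ms / (MU0 * ms**2)
        out = effective_field(np.zeros(3), s, m, metglas)
        assert out[2] == pytest.approx(expected, rel=1e-12)


class TestSelfConsistentState:
    def test_zero_everything(self, metglas):
        st_ = self_consistent_state(np.zeros(3), None, metglas)
        assert np.allclose(st_.magnetization, 0.0)

    def test_linear_demagnetization_limit(self, metglas):
        # closed form: M/H_applied -> χ0 / (1 + χ0/3) for tiny fields
        chi0 = metglas.initial_susceptibility
        h = np.array([0, 0, 0.5])
        st_ = self_consistent_state(h, None, metglas)
        expected = chi0 / (1.0 + chi0 / 3.0)
        assert st_.magnetization[2] / h[2] == pytest.approx(expected, rel=1e-3)

    def test_deep_saturation_internal_field(self, metglas):
        ms = metglas.saturation_magnetization
        h = np.array([0, 0, 5.0 / MU0])
        st_ = self_consistent_state(h, None, metglas)
        assert st_.internal_field[2] == pytest.approx(h[2] - ms / 3.0, rel=1e-3)

    def test_magnetization_parallel_to_effective_field(self, metglas):
        st_ = self_consistent_state(np.array([1e4, 2e4, 3e4]), None, metglas)
        cross = np.cross(st_.magnetization, st_.effective_field)
        assert np.linalg.norm(cross) < 1e-6 * np.linalg.norm(
            st_.magnetization
        ) * np.linalg.norm(st_.effective_field)

    def test_residual_below_tolerance(self, metglas):
        st_ = self_consistent_state(np.array([0, 0, 2e5]), None, metglas)
        assert st_.residual < 1e-10

    def test_axial_solver_agrees_with_general_solver(self, metglas):
        h = np.array([0.0, 5e4, 1e5, 2.5e5, 5e5])
        m_axial = solve_axial_magnetization(h, metglas)
        for hz, mz in zip(h, m_axial):
            st_ = self_consistent_state(np.array([0, 0, hz]), None, metglas)
            assert mz == pytest.approx(st_.magnetization[2], rel=1e-7, abs=1e-3)


@pytest.fixture(scope="module")
def curve(metglas):
    return bias_sweep(np.linspace(-1.0, 1.0, 201), metglas)


class TestBiasSweep:
    def test_even_symmetry_and_zero_at_origin(self, curve):
        lam = curve.lambda_parallel
        assert lam[100] == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(lam, lam[::-1], rtol=1e-9, atol=1e-15)

    def test_saturates_at_lambda_s(self, curve, metglas):
        assert np.max(curve.lambda_parallel) == pytest.approx(12e-6, rel=5e-3)
        assert np.max(np.abs(curve.lambda_parallel)) <= 12e-6 * (1 + 1e-9)

    def test_optimum_in_expected_window(self, curve):
        assert 0.15 < curve.optimum_bias < 0.35
        lo, hi = curve.optimum_window
        assert lo <= curve.optimum_bias <= hi

    def test_optimum_matches_independent_dense_scan(self, curve, metglas):
        # brute-force oracle: per-point general solver, central differences
        b = curve.bias_axis
        lam = np.array(
            [
                self_consistent_state(np.array([0, 0, bb / MU0]), None, metglas).strain_me[2]
                for bb in b
            ]
        )
        dlam = np.gradient(lam, b)
        pos = b > 0
        oracle = b[pos][np.argmax(dlam[pos])]
        assert curve.optimum_bias == pytest.approx(oracle, abs=1e-12)

    def test_equals_closed_composition(self, curve, metglas):
        # λ from the sweep equals me_strain∘magnetization_of_field at the
        # converged effective field (stress feedback disabled)
        ms = metglas.saturation_magnetization
        for i in (110, 130, 160):
            bb = curve.bias_axis[i]
            st_ = self_consistent_state(np.array([0, 0, bb / MU0]), None, metglas)
            m = magnetization_of_field(st_.effective_field, metglas)
            assert me_strain(m, metglas)[2] == pytest.approx(st_.strain_me[2], rel=1e-8)
            assert curve.lambda_parallel[i] == pytest.approx(
                metglas.saturation_magnetostriction * (st_.magnetization[2] / ms) ** 2,
                rel=1e-6,
            )

    def test_parameter_recovery_from_noiseless_curve(self, metglas):
        """Fitting λs and χ0 to a synthetic bias curve recovers the inputs."""
        import dataclasses

        b = np.linspace(-0.6, 0.6, 61)
        target = bias_sweep(b, metglas).lambda_parallel

        def model(bb, lam_s, chi0):
            mat = dataclasses.replace(
                metglas,
                saturation_magnetostriction=lam_s,
                initial_susceptibility=chi0,
            )
            return bias_sweep(bb, mat).lambda_parallel

        popt, _ = curve_fit(model, b, target, p0=[8e-6, 150.0])
        assert popt[0] == pytest.approx(12e-6, rel=0.01)
        assert popt[1] == pytest.approx(200.0, rel=0.01)
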