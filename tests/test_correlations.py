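"""Correlation-function paths: exact quantum oracle, closed forms,
quadrature, discrete sums, and their symmetries."""

import numpy as np
import pytest
from scipy.linalg import expm

from ndcrate import (
    DiscreteModeSet,
    OhmicDeltaParams,
    ThermoState,
    add_ohmic_damping,
    closed_form_D,
    closed_form_F,
    closed_form_g,
    corr_closed_form,
    corr_from_discrete,
    corr_from_spectrum,
    parametric_triple,
    resample,
    table2_case,
    triple_from_modes,
)
from ndcrate.correlations import TimeGrid
from ndcrate.units import REDUCED


def exact_two_mode_correlation(omega, g, f_raw, beta, times, nf=14):
    """Numerically exact C(t) for two displaced modes with momentum coupling.

    Truncated-Fock-space propagation: C(t) = Tr{ρ e^{iH1t} V12 e^{-iH2t} V21}
    with V12 = i Σ f_raw_j p_j and H2 = H1 + Σ ω_j g_j (b_j + b_j†).
    Independent of every analytic formula in the package (ħ = 1).
    """
    a = np.diag(np.sqrt(np.arange(1, nf)), 1)
    eye = np.eye(nf)
    b = [np.kron(a, eye), np.kron(eye, a)]
    h1 = sum(omega[j] * (b[j].T.conj() @ b[j]) for j in range(2))
    h2 = h1 + sum(omega[j] * g[j] * (b[j] + b[j].T.conj()) for j in range(2))
    p = [1j * np.sqrt(omega[j] / 2.0) * (b[j].T.conj() - b[j]) for j in range(2)]
    v12 = sum(1j * f_raw[j] * p[j] for j in range(2))
    rho = expm(-beta * h1)
    rho /= np.trace(rho).real
    out = []
    for t in times:
        u1 = expm(1j * h1 * t)
        u2 = expm(-1j * h2 * t)
        out.append(np.trace(rho @ u1 @ v12 @ u2 @ v12.T.conj()))
    return np.array(out)


class TestExactOracle:
    def test_assembled_integrand_matches_fock_space_propagation(self):
        """The package's exp(-g)·[D - F²] equals the exact quantum trace.

        The exact trace carries the reorganization phase e^{iλt} because its
        final-state Hamiltonian is referenced to the undisplaced origin; the
        drift-free package convention books that phase with the energy gap.
        """
        omega = np.array([1.0, 2.3])
        g = np.array([0.45, 0.6])
        f_raw = np.array([0.3, -0.5])
        beta = 0.7
        grid = TimeGrid(5.0, 0.25)
        exact = exact_two_mode_correlation(omega, g, f_raw, beta, grid.t, nf=18)
        modes = DiscreteModeSet(omega, g, f_raw / np.sqrt(2.0 * omega))
        c = corr_from_discrete(modes, ThermoState(1.0 / beta, REDUCED), grid, units=REDUCED)
        lam = float(np.sum(g**2 * omega))
        mine = np.exp(1j * lam * grid.t) * np.exp(-c.g) * (c.D - c.F**2)
        # Fock truncation at nf=18 limits agreement to ~6e-5
        assert np.max(np.abs(mine - exact)) < 2e-4

    def test_condon_part_alone_matches_exact_trace_without_coupling(self):
        """exp(-g) alone reproduces the overlap trace (f_raw = 0 analogue)."""
        omega = np.array([1.3, 0.7])
        g = np.array([0.5, 0.35])
        beta = 1.1
        grid = TimeGrid(4.0, 0.2)
        # exact FC correlation: Tr{rho e^{iH1t} e^{-iH2t}}
        nf = 14
        a = np.diag(np.sqrt(np.arange(1, nf)), 1)
        eye = np.eye(nf)
        b = [np.kron(a, eye), np.kron(eye, a)]
        h1 = sum(omega[j] * (b[j].T.conj() @ b[j]) for j in range(2))
        h2 = h1 + sum(omega[j] * g[j] * (b[j] + b[j].T.conj()) for j in range(2))
        rho = expm(-beta * h1)
        rho /= np.trace(rho).real
        exact = np.array(
            [np.trace(rho @ expm(1j * h1 * t) @ expm(-1j * h2 * t)) for t in grid.t]
        )
        modes = DiscreteModeSet(omega, g, np.zeros(2))
        c = corr_from_discrete(modes, ThermoState(1.0 / beta, REDUCED), grid, units=REDUCED)
        lam = float(np.sum(g**2 * omega))
        mine = np.exp(1j * lam * grid.t) * np.exp(-c.g)
        assert np.max(np.abs(mine - exact)) < 5e-5


class TestPathEquivalence:
    @pytest.mark.parametrize("cid", ["I-A", "II-B"])
    def test_closed_form_agrees_with_quadrature(self, cid, grid10):
        nc = table2_case(cid)
        cf = corr_closed_form(nc.params, nc.thermo, grid10)
        qd = corr_from_spectrum(parametric_triple(nc.params, units=REDUCED), nc.thermo, grid10)
        for name in ("g", "F", "D"):
            a, b = getattr(cf, name), getattr(qd, name)
            scale = np.max(np.abs(b)) or 1.0
            assert np.max(np.abs(a - b)) / scale < 1e-6, name

    def test_discrete_sums_equal_spectral_delta_path(self, grid10, theta1):
        modes = DiscreteModeSet([5.0, 2.0], [1.0, 0.4], [2.0, -0.5])
        d1 = corr_from_discrete(modes, theta1, grid10, units=REDUCED)
        d2 = corr_from_spectrum(triple_from_modes(modes, units=REDUCED), theta1, grid10)
        for name in ("g", "F", "D"):
            assert np.max(np.abs(getattr(d1, name) - getattr(d2, name))) < 1e-10


class TestClosedFormG:
    def test_zero_at_t0_under_both_flags(self, theta1, grid10):
        p = table2_case("I-A").params
        for flag in (False, True):
            assert closed_form_g(p, theta1, grid10, use_eq39_approx=flag)[0] == 0.0

    def test_interpolation_approximation_within_few_percent(self, theta1, grid10):
        p = table2_case("I-A").params
        exact = closed_form_g(p, theta1, grid10)
        approx = closed_form_g(p, theta1, grid10, use_eq39_approx=True)
        m = grid10.t >= 0.1
        rel = np.max(np.abs(approx - exact)[m] / np.abs(exact)[m])
        assert rel < 0.02

    def test_reorg_drift_gives_linear_imaginary_part(self):
        # Im g -> -lambda_l*t/hbar + const at long times (Ohmic-only bath)
        p = OhmicDeltaParams(eta=1.3, omega_c=1.0, s_h=0.0, omega_h=5.0)
        th = ThermoState.from_theta(1.0)
        grid = TimeGrid(100.0, 0.05)
        g = closed_form_g(p, th, grid, include_reorg_drift=True)
        sel = grid.t > 50.0
        slope = np.polyfit(grid.t[sel], g.imag[sel], 1)[0]
        assert slope == pytest.approx(-1.3, rel=1e-3)

    def test_single_mode_zero_temperature_recurrence(self):
        # |exp(-g)| is periodic with period 2π/ω_h when T -> 0
        p = OhmicDeltaParams(eta=0.0, omega_c=1.0, s_h=1.0, omega_h=5.0)
        th = ThermoState.from_theta(200.0)
        grid = TimeGrid(2.0 * np.pi / 5.0, 2.0 * np.pi / 5.0 / 400)
        g = closed_form_g(p, th, grid)
        assert abs(np.exp(-g[-1])) == pytest.approx(1.0, abs=1e-10)

    def test_high_temperature_classical_quadratic_onset(self):
        # Re g ≈ λ k_BT t² / ħ² at short times for θ -> 0
        th = ThermoState.from_theta(0.05)
        p = OhmicDeltaParams(eta=2.0, omega_c=1.0, s_h=0.0, omega_h=5.0)
        grid = TimeGrid(0.05, 0.05 / 200)
        g = closed_form_g(p, th, grid)
        lam, kbt = 2.0, 20.0
        classical = lam * kbt * grid.t**2
        sel = grid.t > 0
        assert np.max(np.abs(g.real[sel] / classical[sel] - 1.0)) < 0.02

    def test_real_part_monotone_for_ohmic_at_moderate_theta(self):
        p = OhmicDeltaParams(eta=1.0, omega_c=1.0, s_h=0.0, omega_h=5.0)
        for theta in (0.5, 1.0):
            g = closed_form_g(p, ThermoState.from_theta(theta), TimeGrid(20.0, 0.01))
            assert np.all(np.diff(g.real) >= -1e-12)


class TestClosedFormDF:
    def test_zero_density_gives_zero_kernel(self, theta1, grid10):
        p = OhmicDeltaParams(eta=1.0, omega_c=1.0, s_h=1.0, omega_h=5.0)
        assert np.all(closed_form_D(p, theta1, grid10) == 0)
        assert np.all(closed_form_F(p, theta1, grid10) == 0)

    def test_d0_is_real_and_equals_thermal_weight(self, theta1, grid10):
        nc = table2_case("I-A")
        d = closed_form_D(nc.params, theta1, grid10)
        # delta part: s_D ω_h² coth(βω_h/2); Ohmic part zero for I-A
        expect = 4.0 * 25.0 / np.tanh(0.5 * 5.0)
        assert d[0].imag == 0.0
        assert d[0].real == pytest.approx(expect, rel=1e-12)

    def test_f_vanishes_at_t0_and_is_linear_in_cross_density(self, theta1, grid10):
        b = table2_case("I-B")
        c = table2_case("I-C")
        fb = closed_form_F(b.params, theta1, grid10)
        fc = closed_form_F(c.params, theta1, grid10)
        assert fb[0] == 0.0
        # negating both cross components negates F pointwise (linearity)
        p_neg = OhmicDeltaParams(
            eta=1.0, omega_c=1.0, s_h=1.0, omega_h=5.0, eta_D=15.0, s_D=1.0,
            eta_F=-2.0, s_F=-1.0,
        )
        assert np.allclose(closed_form_F(p_neg, theta1, grid10), -fb, atol=1e-14)
        # flipping s_F alone flips only the delta part: (F_B + F_C)/2 is Ohmic
        f_ohmic = 0.5 * (fb + fc)
        p_ohmic_only_scaled = OhmicDeltaParams(
            eta=1.0, omega_c=1.0, s_h=0.0, omega_h=5.0, eta_D=15.0, eta_F=2.0
        )
        assert np.allclose(f_ohmic, closed_form_F(p_ohmic_only_scaled, theta1, grid10), atol=1e-12)

    def test_delta_only_quadrature_equals_closed_form(self, theta1, grid10):
        # eta_D = 0: the NDC kernel is a pure analytic point mass both ways
        p = OhmicDeltaParams(eta=1.0, omega_c=1.0, s_h=1.0, omega_h=5.0, s_D=4.0, s_F=2.0)
        d_cf = closed_form_D(p, theta1, grid10)
        d_q = corr_from_spectrum(parametric_triple(p, units=REDUCED), theta1, grid10).D
        assert np.max(np.abs(d_cf - d_q)) < 1e-10


class TestSymmetryRules:
    def test_time_reversal_of_kernels(self, theta1):
        """g(-t)=g*(t), D(-t)=D*(t), F(-t)=-F*(t) from the defining sums."""
        modes = DiscreteModeSet([5.0, 1.7], [0.8, 0.3], [1.1, -0.4])
        grid = TimeGrid(5.0, 0.05)
        c = corr_from_discrete(modes, theta1, grid, units=REDUCED)
        # negative-time evaluation via the same sums with t -> -t
        w = modes.omega
        ch = 1.0 / np.tanh(0.5 * theta1.beta * w)
        tneg = -grid.t
        s_fc, s_d, s_f = modes.g**2, modes.f**2, modes.g * modes.f
        cosm = np.cos(tneg[:, None] * w)
        sinm = np.sin(tneg[:, None] * w)
        g_neg = (1 - cosm) @ (s_fc * ch) + 1j * (sinm @ s_fc)
        d_neg = cosm @ (s_d * w**2 * ch) - 1j * (sinm @ (s_d * w**2))
        f_neg = 1j * ((1 - cosm) @ (s_f * w * ch)) - sinm @ (s_f * w)
        assert np.allclose(g_neg, np.conj(c.g), atol=1e-12)
        assert np.allclose(d_neg, np.conj(c.D), atol=1e-12)
        assert np.allclose(f_neg, -np.conj(c.F), atol=1e-12)


class TestUtilities:
    def test_empty_mode_set_warns_and_returns_zero(self, theta1):
        grid = TimeGrid(1.0, 0.01)
        with pytest.warns(UserWarning, match="empty"):
            c = corr_from_discrete(DiscreteModeSet([], [], []), theta1, grid, units=REDUCED)
        assert np.all(c.g == 0) and np.all(c.D == 0)

    def test_ohmic_addition_damps_only_the_lineshape(self, theta1):
        modes = DiscreteModeSet([5.0], [1.0], [2.0])
        grid = TimeGrid(10.0, 0.01)
        c0 = corr_from_discrete(modes, theta1, grid, units=REDUCED)
        c1 = add_ohmic_damping(c0, 1.0, 1.0)
        assert not c0.damped and c1.damped
        assert np.allclose(c1.D, c0.D) and np.allclose(c1.F, c0.F)
        assert np.all(c1.g.real[1:] > c0.g.real[1:] - 1e-15)

    def test_resample_reproduces_closed_form(self, theta1):
        nc = table2_case("I-A")
        coarse = corr_closed_form(nc.params, nc.thermo, TimeGrid(10.0, 0.02))
        fine_grid = TimeGrid(10.0, 0.004)
        direct = corr_closed_form(nc.params, nc.thermo, fine_grid)
        splined = resample(coarse, fine_grid)
        for name in ("g", "F", "D"):
            a, b = getattr(splined, name), getattr(direct, name)
            assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 1e-5, name
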