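"""Bath spectral densities for nonadiabatic golden-rule rates.

Three spectral densities describe the coupled electron–nuclear problem for a
pair of displaced harmonic surfaces with a momentum (derivative-coupling)
interaction:

* ``J``   — the Franck–Condon density: per-mode weight ω_j² g_j², where g_j is
  the dimensionless vibronic coupling (Huang–Rhys factor S_j = g_j²).
* ``J_D`` — the squared-NDC density: per-mode weight ω_j² f_j², where f_j is
  the dimensionless projection of the first derivative coupling on mode j
  (the momentum-coupling matrix element is purely imaginary, i·f_j carrier).
* ``J_F`` — the NDC–displacement cross density: per-mode weight ω_j² g_j f_j,
  real but not sign-definite.

Frequencies are carried as mode energies ħω (cm^-1 in physical units).  The
parametric family is an Ohmic density with exponential cutoff plus a single
high-frequency delta peak,

    J(ω)   = η   ħω e^{-ω/ω_c} + s_h ħ²ω_h² δ(ħω - ħω_h),
    J_D(ω) = η_D ħω e^{-ω/ω_c} + s_D ħ²ω_h² δ(ħω - ħω_h),
    J_F(ω) = η_F ħω e^{-ω/ω_c} + s_F ħ²ω_h² δ(ħω - ħω_h),

a prefactor convention pinned by the reorganization-energy mapping
λ_l = η·ħω_c, λ_h = s_h·ħω_h (and D_l = η_D ħω_c, D_h = s_D ħω_h,
F_l = η_F ħω_c, F_h = s_F ħω_h).  Delta peaks are never discretized: they are
carried as (position, weight) pairs and summed analytically downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .units import PHYSICAL, UnitSystem

__all__ = [
    "OhmicDeltaParams",
    "DiscreteModeSet",
    "DeltaPeak",
    "SpectralTriple",
    "TabulatedDensity",
    "parametric_triple",
    "eval_parametric_triple",
    "triple_from_modes",
    "bo_lineshape",
    "bo_normalization",
    "check_cross_bound",
    "CrossBoundReport",
    "reorganization_energy",
]

_SF_RTOL = 1e-9


@dataclass(frozen=True)
class OhmicDeltaParams:
    """Dimensionless parameters of the Ohmic-plus-delta spectral densities.

    ``omega_c`` and ``omega_h`` are energies (ħω_c, ħω_h) in the active unit
    system; in reduced units ``omega_c = 1`` by convention.
    """

    eta: float
    omega_c: float
    s_h: float
    omega_h: float
    eta_D: float = 0.0
    s_D: float = 0.0
    eta_F: float = 0.0
    s_F: float = 0.0

    def __post_init__(self) -> None:
        if not (self.omega_c > 0):
            raise ValidationError("omega_c must be > 0")
        if not (self.omega_h > 0):
            raise ValidationError("omega_h must be > 0")
        for name in ("eta", "s_h", "eta_D", "s_D"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        # The delta parts originate from a single mode: s_F^2 = s_h * s_D.
        target = self.s_h * self.s_D
        if not math.isclose(self.s_F**2, target, rel_tol=_SF_RTOL, abs_tol=1e-12):
            raise ValidationError(
                f"s_F^2 = {self.s_F**2:g} must equal s_h*s_D = {target:g} "
                "(single-mode origin of the delta peaks)"
            )
        if abs(self.eta_F) > self.eta_D / 2.0 + 1e-12 * max(1.0, self.eta_D):
            raise ValidationError(
                f"|eta_F| = {abs(self.eta_F):g} exceeds eta_D/2 = {self.eta_D / 2:g}"
            )

    # Energy-unit mappings (Table-1-style)
    @property
    def lambda_l(self) -> float:
        return self.eta * self.omega_c

    @property
    def lambda_h(self) -> float:
        return self.s_h * self.omega_h

    @property
    def D_l(self) -> float:
        return self.eta_D * self.omega_c

    @property
    def D_h(self) -> float:
        return self.s_D * self.omega_h

    @property
    def F_l(self) -> float:
        return self.eta_F * self.omega_c

    @property
    def F_h(self) -> float:
        return self.s_F * self.omega_h


@dataclass(frozen=True)
class DiscreteModeSet:
    """Per-mode frequencies and couplings.

    ``omega``: mode energies ħω_j (> 0); ``g``: signed dimensionless vibronic
    couplings (only g² enters J); ``f``: signed dimensionless NDC projections.
    """

    omega: np.ndarray
    g: np.ndarray
    f: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "omega", np.atleast_1d(np.asarray(self.omega, float)))
        object.__setattr__(self, "g", np.atleast_1d(np.asarray(self.g, float)))
        object.__setattr__(self, "f", np.atleast_1d(np.asarray(self.f, float)))
        n = self.omega.size
        if self.g.size != n or self.f.size != n:
            raise ValidationError("omega, g and f must have the same length")
        if n and not np.all(np.isfinite(self.omega) & np.isfinite(self.g) & np.isfinite(self.f)):
            raise ValidationError("mode entries must be finite")
        if n and not np.all(self.omega > 0):
            bad = int(np.argmin(self.omega))
            raise ValidationError(f"mode {bad}: frequency must be > 0, got {self.omega[bad]:g}")
        if self.labels is not None and len(self.labels) != n:
            raise ValidationError("labels length must match the number of modes")

    def __len__(self) -> int:
        return int(self.omega.size)

    @property
    def huang_rhys(self) -> np.ndarray:
        return self.g**2

    def reorganization_energy(self) -> float:
        """λ = Σ_j g_j² ħω_j in the active energy unit."""
        return float(np.sum(self.g**2 * self.omega))

    def ndc_strength(self) -> float:
        """Σ_j f_j² ħω_j — the discrete analogue of D_l + D_h."""
        return float(np.sum(self.f**2 * self.omega))


@dataclass(frozen=True)
class DeltaPeak:
    """A point mass shared by the three densities at one mode energy.

    Weights are the dimensionless strengths (s_fc = g², s_d = f², s_f = g·f);
    the density weight of channel X at ω_j is ``s_X · ω_j²``.
    """

    omega: float
    s_fc: float
    s_d: float
    s_f: float


def _zero_density(omega: np.ndarray) -> np.ndarray:
    return np.zeros_like(np.asarray(omega, float))


@dataclass(frozen=True)
class SpectralTriple:
    """Evaluable triple (J, J_D, J_F) = continuous parts + shared delta peaks.

    ``J``, ``J_D``, ``J_F`` evaluate the *continuous* part at ω >= 0 (the
    delta peaks are carried analytically in ``deltas``).  ``kind`` is one of
    ``parametric | discrete | bo_broadened | tabulated``.  ``bo_tail``
    holds the exact coefficients (C_J, C_D, C_F) of the ω^-3 far tail of a
    BO-broadened triple, used for analytic tail corrections in quadrature.
    """

    kind: str
    J_cont: Callable[[np.ndarray], np.ndarray]
    JD_cont: Callable[[np.ndarray], np.ndarray]
    JF_cont: Callable[[np.ndarray], np.ndarray]
    deltas: tuple[DeltaPeak, ...] = ()
    gamma: Optional[float] = None
    units: UnitSystem = PHYSICAL
    omega_scale: float = 1.0  # characteristic continuum scale (for cutoffs)
    bo_tail: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    params: Optional[OhmicDeltaParams] = None

    def _eval(self, fn, omega):
        om = np.asarray(omega, float)
        if np.any(om < 0):
            raise ValidationError("spectral densities are defined for omega >= 0")
        return fn(om)

    def J(self, omega):
        return self._eval(self.J_cont, omega)

    def J_D(self, omega):
        return self._eval(self.JD_cont, omega)

    def J_F(self, omega):
        return self._eval(self.JF_cont, omega)

    @property
    def has_continuum(self) -> bool:
        """True if any channel has a nonvanishing continuous part."""
        probe = np.linspace(0.1, 10.0, 7) * self.omega_scale
        return bool(
            np.any(self.J_cont(probe) != 0)
            or np.any(self.JD_cont(probe) != 0)
            or np.any(self.JF_cont(probe) != 0)
        )

    @property
    def damps_lineshape(self) -> bool:
        """True if the Franck–Condon channel J has continuous weight.

        Only continuous J weight damps exp(-g) at long times; a purely
        discrete J gives a recurrent integrand with no well-defined rate.
        """
        probe = np.linspace(0.1, 10.0, 7) * self.omega_scale
        return bool(np.any(self.J_cont(probe) > 0))


def parametric_triple(params: OhmicDeltaParams, units: UnitSystem = PHYSICAL) -> SpectralTriple:
    """Build the Ohmic-plus-delta :class:`SpectralTriple` from parameters."""
    ec = params.omega_c

    def _ohmic(eta):
        def f(om):
            return eta * om * np.exp(-om / ec)

        return f

    deltas = ()
    if params.s_h or params.s_D or params.s_F:
        deltas = (DeltaPeak(params.omega_h, params.s_h, params.s_D, params.s_F),)
    return SpectralTriple(
        kind="parametric",
        J_cont=_ohmic(params.eta),
        JD_cont=_ohmic(params.eta_D),
        JF_cont=_ohmic(params.eta_F),
        deltas=deltas,
        units=units,
        omega_scale=ec,
        params=params,
    )


def eval_parametric_triple(params: OhmicDeltaParams, omega):
    """Continuous (Ohmic) parts of the three densities at ``omega``.

    The delta components are *not* spiked onto the returned values; they live
    on ``parametric_triple(params).deltas`` as analytic point masses.
    """
    t = parametric_triple(params)
    return t.J(omega), t.J_D(omega), t.J_F(omega)


def bo_normalization(omega_j: float, gamma: float) -> float:
    """Closed-form normalization A of the Brownian-oscillator lineshape.

    The lineshape is  L(ω) = A·γω / [(ω² - ω_j²)² + γ²ω²]  with
    ∫_0^∞ L dω = 1.  Derived by the u = ω² substitution: the integral is
    elementary for both the underdamped (γ < 2ω_j) and overdamped branches.
    """
    if not (omega_j > 0):
        raise ValidationError("omega_j must be > 0")
    if not (gamma > 0):
        raise ValidationError("gamma must be > 0")
    b = omega_j**2 - gamma**2 / 2.0
    disc = gamma**2 * (omega_j**2 - gamma**2 / 4.0)
    if disc > 0:  # underdamped
        root = math.sqrt(disc)
        integral = (gamma / 2.0) / root * (math.pi / 2.0 + math.atan(b / root))
    elif disc < 0:  # overdamped: real negative roots of u² - 2bu + ω_j⁴
        d = math.sqrt(-disc)
        u_plus, u_minus = b + d, b - d
        integral = (gamma / (4.0 * d)) * math.log(u_minus / u_plus)
    else:  # critically damped
        integral = -gamma / (2.0 * b)
    return 1.0 / integral


def bo_lineshape(omega, omega_j: float, gamma: float):
    """Normalized Brownian-oscillator density replacing a delta at ω_j.

    Linear as ω→0⁺, Lorentzian-like near ω_j, and decaying as ω⁻³ at large
    ω; ∫_0^∞ dω = 1 with the closed-form constant of
    :func:`bo_normalization` (no runtime quadrature).
    """
    om = np.asarray(omega, float)
    if np.any(om < 0):
        raise ValidationError("omega must be >= 0")
    a = bo_normalization(omega_j, gamma)
    return a * gamma * om / ((om**2 - omega_j**2) ** 2 + gamma**2 * om**2)


def triple_from_modes(
    modes: DiscreteModeSet,
    broadening: Optional[float] = None,
    units: UnitSystem = PHYSICAL,
) -> SpectralTriple:
    """Spectral triple from a discrete mode set.

    Without ``broadening`` the result is a pure point-mass triple (kind
    ``discrete``); with a friction γ > 0 each point mass is replaced by the
    normalized BO lineshape centered at ω_j with the same integrated weight.
    """
    if broadening is not None and not (broadening > 0):
        raise ValidationError("broadening friction gamma must be > 0 when given")
    w_fc = modes.g**2 * modes.omega**2
    w_d = modes.f**2 * modes.omega**2
    w_f = modes.g * modes.f * modes.omega**2

    if broadening is None:
        deltas = tuple(
            DeltaPeak(float(om), float(g) ** 2, float(f) ** 2, float(g) * float(f))
            for om, g, f in zip(modes.omega, modes.g, modes.f)
        )
        scale = float(np.max(modes.omega)) if len(modes) else 1.0
        return SpectralTriple(
            kind="discrete",
            J_cont=_zero_density,
            JD_cont=_zero_density,
            JF_cont=_zero_density,
            deltas=deltas,
            units=units,
            omega_scale=scale,
        )

    gam = float(broadening)
    if len(modes) == 0:
        return SpectralTriple(
            kind="bo_broadened",
            J_cont=_zero_density,
            JD_cont=_zero_density,
            JF_cont=_zero_density,
            gamma=gam,
            units=units,
        )
    norms = np.array([bo_normalization(float(om), gam) for om in modes.omega])

    def _mk(weights):
        w = np.asarray(weights, float)

        def f(om):
            om = np.atleast_1d(np.asarray(om, float))
            # (n_omega, n_modes) kernel; modest sizes, evaluated lazily
            denom = (om[:, None] ** 2 - modes.omega[None, :] ** 2) ** 2 + (
                gam * om[:, None]
            ) ** 2
            out = (w * norms * gam)[None, :] * om[:, None] / denom
            return out.sum(axis=1)

        return f

    # Far-tail asymptotics: L_j(E) -> A_j Γ/E³ · [1 + (2E_j² − Γ²)/E² + ...],
    # so each channel X has J_X(E) ≈ C1_X/E³ + C2_X/E⁵ beyond the resolved
    # region; the coefficients feed analytic tail corrections downstream.
    c2_factor = 2.0 * modes.omega**2 - gam**2
    tail = tuple(
        float(np.sum(w * norms * gam)) for w in (w_fc, w_d, w_f)
    ) + tuple(float(np.sum(w * norms * gam * c2_factor)) for w in (w_fc, w_d, w_f))
    return SpectralTriple(
        kind="bo_broadened",
        J_cont=_mk(w_fc),
        JD_cont=_mk(w_d),
        JF_cont=_mk(w_f),
        gamma=gam,
        units=units,
        omega_scale=float(np.max(modes.omega)),
        bo_tail=tail,
    )


@dataclass(frozen=True)
class TabulatedDensity:
    """User-supplied density on a monotone ω grid, linearly interpolated.

    Evaluates to zero beyond the last tabulated point (explicit high-ω
    cutoff); intended for, e.g., simulation-derived densities.
    """

    omega: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, float)
        val = np.asarray(self.values, float)
        if om.ndim != 1 or om.size < 2 or val.shape != om.shape:
            raise ValidationError("need matching 1-d omega/value tables with >= 2 rows")
        if np.any(np.diff(om) <= 0):
            raise ValidationError("omega table must be strictly increasing")
        if om[0] < 0:
            raise ValidationError("omega table must be nonnegative")
        object.__setattr__(self, "omega", om)
        object.__setattr__(self, "values", val)

    def __call__(self, omega):
        return np.interp(np.asarray(omega, float), self.omega, self.values, left=0.0, right=0.0)


@dataclass(frozen=True)
class CrossBoundReport:
    """Result of the cross-coupling magnitude check."""

    passed: bool
    margin: float  # most negative slack; >= 0 means pass
    detail: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def check_cross_bound(obj) -> CrossBoundReport:
    """Check that the cross density magnitude is consistent with J and J_D.

    For parametric input the Ohmic part must satisfy |η_F| <= η_D/2 and the
    delta part s_F² = s_h·s_D (single-mode saturation).  For a constructed
    triple the pointwise Cauchy–Schwarz bound |J_F(ω)| <= sqrt(J(ω)·J_D(ω))
    is checked on the continuum and per point mass; a triple built from any
    discrete mode set satisfies it by construction.
    """
    if isinstance(obj, dict):
        # raw parameter probe, e.g. {"eta_D": 4, "eta_F": 2.01}; lets callers
        # test combinations the OhmicDeltaParams constructor would reject
        eta_d = float(obj.get("eta_D", 0.0))
        eta_f = float(obj.get("eta_F", 0.0))
        margin = eta_d / 2.0 - abs(eta_f)
        ok = margin >= -1e-12 * max(1.0, eta_d)
        return CrossBoundReport(ok, margin, f"eta_D/2 - |eta_F| = {margin:g}")
    if isinstance(obj, OhmicDeltaParams):
        margin = obj.eta_D / 2.0 - abs(obj.eta_F)
        ok = margin >= -1e-12 * max(1.0, obj.eta_D)
        return CrossBoundReport(ok, margin, f"eta_D/2 - |eta_F| = {margin:g}")
    if isinstance(obj, DiscreteModeSet):
        obj = triple_from_modes(obj)
    if not isinstance(obj, SpectralTriple):
        raise ValidationError("expected OhmicDeltaParams, DiscreteModeSet or SpectralTriple")
    margins = []
    if obj.params is not None:
        margins.append(obj.params.eta_D / 2.0 - abs(obj.params.eta_F))
    else:
        grid = np.linspace(1e-3, 8.0, 4001) * obj.omega_scale
        j, jd, jf = obj.J(grid), obj.J_D(grid), obj.J_F(grid)
        slack = np.sqrt(np.maximum(j * jd, 0.0)) - np.abs(jf)
        scale = max(np.max(np.abs(jf), initial=0.0), 1e-300)
        margins.append(float(np.min(slack, initial=np.inf)) / scale if np.any(jf) else np.inf)
    for pk in obj.deltas:
        bound = math.sqrt(max(pk.s_fc * pk.s_d, 0.0))
        margins.append(bound - abs(pk.s_f) + 1e-12 * max(1.0, bound))
    margin = float(min(margins)) if margins else math.inf
    ok = margin >= -1e-9
    return CrossBoundReport(ok, margin, f"tightest Cauchy-Schwarz slack = {margin:g}")


def reorganization_energy(obj, units: UnitSystem = PHYSICAL) -> float:
    """Total reorganization energy λ = ∫ J(ω)/ω dω + Σ_j s_fc,j ω_j.

    For parametric input this equals η·ħω_c + s_h·ħω_h exactly; for a
    discrete set it is the direct per-mode sum Σ g_j² ħω_j.
    """
    if isinstance(obj, OhmicDeltaParams):
        return obj.lambda_l + obj.lambda_h
    if isinstance(obj, DiscreteModeSet):
        return obj.reorganization_energy()
    if not isinstance(obj, SpectralTriple):
        raise ValidationError("expected OhmicDeltaParams, DiscreteModeSet or SpectralTriple")
    lam = sum(pk.s_fc * pk.omega for pk in obj.deltas)
    if obj.params is not None:
        lam += obj.params.lambda_l
    else:
        from scipy.integrate import quad

        val, err = quad(
            lambda om: obj.J_cont(np.array([om]))[0] / om,
            0.0,
            np.inf,
            limit=400,
        )
        if not np.isfinite(val) or (abs(val) > 0 and err > 1e-6 * abs(val) + 1e-12):
            raise ValidationError(
                f"reorganization integral did not converge (value {val:g}, err {err:g})"
            )
        lam += val
    return float(lam)
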