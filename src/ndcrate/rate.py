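"""Golden-rule rate from the assembled bath correlation function.

The composite integrand for a transition with adiabatic energy gap ΔE
(E₁ − E₂ > 0 downhill) is

    C(t) = exp(i ΔE t/ħ) · exp(−g(t)) · [ D(t)/ħ² − (F(t)/ħ)² ]

and the rate is the one-sided real-part integral

    k = 2 Re ∫_0^∞ C(t) dt ,

the conventional form equivalent to the full two-sided Fourier integral by
the Hermitian symmetry of the integrand.  The Condon reference rate freezes
the NDC kernel at its t = 0 value (which is D(0)/ħ²; F(0) = 0):

    k_C = 2 (D(0)/ħ²) Re ∫_0^∞ exp(i ΔE t/ħ − g(t)) dt .

Integration is trapezoidal on the uniform grid with a coarse-grid
(2·dt) comparison; the reported rate is the Richardson-extrapolated value
and the difference is kept as an error estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .correlations import CorrelationSet
from .errors import ConvergenceError, ValidationError

__all__ = [
    "RateInput",
    "RateResult",
    "assemble_integrand",
    "rate",
    "condon_rate",
    "gap_scan",
]

_TAIL_TOL = 1e-6


@dataclass(frozen=True)
class RateInput:
    """Gap, correlation set and integration controls for one rate.

    ``gaussian_sigma`` multiplies the integrand by exp(−t²/2σ²); this is a
    non-physical apodization for exploratory use with undamped discrete
    baths and is off by default.
    """

    gap: float
    corr: CorrelationSet
    tail_tol: float = _TAIL_TOL
    gaussian_sigma: Optional[float] = None
    allow_undamped: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.gap):
            raise ValidationError("gap must be finite")
        hbar = self.corr.hbar
        dt = self.corr.grid.dt
        omega_fast = abs(self.gap) / hbar
        if dt > 2.0 * np.pi / (20.0 * omega_fast + 1e-300):
            warnings.warn(
                f"dt = {dt:g} under-resolves the gap phase (period {2*np.pi/omega_fast:g}); "
                "results may be inaccurate",
                stacklevel=2,
            )


@dataclass
class RateResult:
    """Computed rate with convergence diagnostics.

    ``integrand_tail`` is the relative magnitude of the damped non-Condon
    envelope at the end of the grid; ``imag_residual`` the imaginary part of
    the reconstructed two-sided integral relative to |k| (consistency of the
    Hermitian symmetry rules); ``richardson_err`` the |fine − coarse|/3
    trapezoid estimate.
    """

    k: float
    k_condon: float
    integrand_tail: float
    imag_residual: float
    richardson_err: float
    converged: bool
    meta: dict = field(default_factory=dict)


def assemble_integrand(corr: CorrelationSet, gap: float, hbar: Optional[float] = None):
    """Composite integrand C(t) on the positive-t grid."""
    hbar = corr.hbar if hbar is None else hbar
    t = corr.t
    return np.exp(1j * gap * t / hbar - corr.g) * (corr.D - corr.F**2)


def _trapz_extrap(y: np.ndarray, dt: float) -> tuple[complex, float]:
    fine = np.trapezoid(y, dx=dt)
    coarse = np.trapezoid(y[::2], dx=2.0 * dt)
    err = abs(fine - coarse) / 3.0
    return fine + (fine - coarse) / 3.0, err


def _check_damping(inp: RateInput) -> None:
    if inp.corr.damped or inp.gaussian_sigma is not None or inp.allow_undamped:
        return
    raise ConvergenceError(
        "the bath has no continuous Franck-Condon weight: exp(-g) does not decay and "
        "the rate integral has no well-defined limit. Add environmental broadening "
        "(an Ohmic component or Brownian-oscillator friction), or pass gaussian_sigma "
        "for an explicitly non-physical apodized estimate."
    )


def _tail_fraction(corr: CorrelationSet, weight: np.ndarray) -> float:
    mag = np.abs(weight)
    scale = float(mag.max(initial=0.0))
    if scale == 0.0:
        return 0.0
    n_tail = max(2, weight.size // 50)
    return float(mag[-n_tail:].max() / scale)


def _one_rate(inp: RateInput, bracket: np.ndarray) -> tuple[float, float, float, float]:
    corr = inp.corr
    hbar = corr.hbar
    t = corr.t
    dt = corr.grid.dt
    damp = np.ones_like(t) if inp.gaussian_sigma is None else np.exp(-0.5 * (t / inp.gaussian_sigma) ** 2)
    c_pos = np.exp(1j * inp.gap * t / hbar - corr.g) * bracket * damp
    i_pos, rich = _trapz_extrap(c_pos, dt)
    k = 2.0 * i_pos.real
    # reconstruct the negative branch from the stored symmetry rules:
    # g(-t) = g*(t), D(-t) = D*(t), F(-t) = -F*(t)  =>  bracket(-t) = bracket*(t)
    c_neg = np.exp(-1j * inp.gap * t / hbar - np.conj(corr.g)) * np.conj(bracket) * damp
    i_neg, _ = _trapz_extrap(c_neg, dt)
    two_sided = i_pos + i_neg
    imag_residual = abs(two_sided.imag) / max(abs(k), 1e-300)
    tail = _tail_fraction(corr, (np.exp(-corr.g.real) * np.abs(bracket) * damp))
    return k, tail, imag_residual, rich


def rate(inp: RateInput) -> RateResult:
    """Full non-Condon golden-rule rate for one energy gap."""
    _check_damping(inp)
    corr = inp.corr
    bracket = corr.D - corr.F**2
    k, tail, imres, rich = _one_rate(inp, bracket)
    d0 = corr.D[0].real
    kc, _, _, _ = _one_rate(inp, np.full(corr.t.size, d0, complex))
    converged = tail < inp.tail_tol and imres < 1e-6
    if tail >= inp.tail_tol:
        warnings.warn(
            f"integrand tail {tail:.2e} above tolerance {inp.tail_tol:g}; "
            "increase t_max or add broadening",
            stacklevel=2,
        )
    if inp.gap <= 0:
        warnings.warn(
            "gap <= 0: the quasi-adiabatic approximation may not be justified for "
            "small or uphill gaps",
            stacklevel=2,
        )
    return RateResult(
        k=k,
        k_condon=kc,
        integrand_tail=tail,
        imag_residual=imres,
        richardson_err=rich,
        converged=converged,
        meta={"gap": inp.gap, "method": corr.method, "source": corr.meta.get("source")},
    )


def condon_rate(inp: RateInput) -> float:
    """Reference rate with the NDC kernel frozen at t = 0 (coupling D(0))."""
    _check_damping(inp)
    d0 = inp.corr.D[0].real
    k, _, _, _ = _one_rate(inp, np.full(inp.corr.t.size, d0, complex))
    return k


def gap_scan(
    corr: CorrelationSet,
    gaps: Sequence[float],
    tail_tol: float = _TAIL_TOL,
    gaussian_sigma: Optional[float] = None,
    allow_undamped: bool = False,
) -> pd.DataFrame:
    """Rates over a gap grid, reusing the correlation set.

    The gap enters only through the phase factor, so g, F, D are evaluated
    once.  Returns a table with columns ``gap, k, k_condon, ln_k, converged``
    (``ln_k`` is NaN where k <= 0); per-point failures are flagged, not
    fatal.
    """
    gaps = np.asarray(gaps, float)
    if gaps.ndim != 1 or gaps.size == 0:
        raise ValidationError("gap grid must be a nonempty 1-d sequence")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gap in gaps:
            inp = RateInput(gap, corr, tail_tol, gaussian_sigma, allow_undamped)
            try:
                res = rate(inp)
                rows.append((gap, res.k, res.k_condon, res.converged))
            except ConvergenceError:
                if not allow_undamped and gaussian_sigma is None:
                    raise
                rows.append((gap, math.nan, math.nan, False))
    df = pd.DataFrame(rows, columns=["gap", "k", "k_condon", "converged"])
    with np.errstate(invalid="ignore", divide="ignore"):
        df.insert(3, "ln_k", np.log(df["k"].to_numpy()))
    return df
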