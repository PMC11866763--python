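# Methods

## Model and rate expression

The package computes golden-rule rates between two electronic states whose
coupling operator is linear in nuclear momenta (the first nonadiabatic
derivative coupling, NDC, evaluated at the initial state's minimum — the
quasi-adiabatic picture), with every nuclear and environmental degree of
freedom a displaced harmonic oscillator: ω_j,2 = ω_j,1, coordinates shifted
by d_j.  With F̃_j = i·f_j the purely imaginary momentum-coupling matrix
element of mode j (real adiabatic wavefunctions) and g_j = d_j√(ω_j/2ħ)
the vibronic coupling, a second-order (exact, for this Hamiltonian)
evaluation of the bath trace by Gaussian/Wick factorization gives the
composite correlation function

    C(t) = e^{−g(t)} [ D(t)/ħ² − (F(t)/ħ)² ]

with, per mode (n̄ the Bose occupation),

    g(t) = Σ g_j² [ coth(βħω_j/2)(1 − cos ω_j t) + i sin ω_j t ]
    D(t) = Σ f_j² (ħω_j)² [ coth(βħω_j/2) cos ω_j t − i sin ω_j t ]
    F(t) = Σ g_j f_j ħω_j [ i coth(βħω_j/2)(1 − cos ω_j t) − sin ω_j t ]

and k(ΔE) = 2 Re ∫₀^∞ e^{iΔEt/ħ} C(t) dt, with ΔE the adiabatic gap.
The derivation was cross-validated against a numerically exact truncated
Fock-space propagation of a two-mode model (tests/test_correlations.py);
agreement is limited only by the oracle's truncation (~1e-5).

Two structural consequences fall out of the derivation and are treated as
facts by the package: F(0) = 0, so the Condon reference rate uses the
effective coupling D(0) alone; and F(−t) = −F*(t) (anti-Hermitian), while
F², D, g and hence C(t) are Hermitian under time reversal — which is what
the reality of the rate requires.

### Gap and drift convention

Some authors fold the reorganization phase into the lineshape exponent
(Im g → −λt/ħ at long times) and correspondingly measure the gap from the
reorganization-shifted origin.  The package's canonical g is drift-free and
its gap is the adiabatic gap; this makes detailed balance take the textbook
KMS form k(Δ)/k(−Δ) = e^{βΔ} and the high-temperature Condon limit reduce
to the Marcus expression with activation (ΔE − λ)²/4λk_BT.  The
drift-inclusive convention is available via `include_reorg_drift=True` on
the g evaluators; the two differ only by a λ shift of the gap.

## Spectral densities

Continuum limits are expressed through three densities (ω carried as an
energy E = ħω internally): J with per-mode weight ω²g², J_D with ω²f²,
J_F with ω²gf.  The parametric family is Ohmic-with-exponential-cutoff
plus one delta peak; the Ohmic prefactor convention J = η·ħω·e^{−ω/ω_c} is
pinned by the reorganization mapping λ_l = ∫J/ω dω = η·ħω_c, which also
fixes D_l = η_D ħω_c, F_l = η_F ħω_c and the delta-side mappings
λ_h = s_h ħω_h, D_h = s_D ħω_h, F_h = s_F ħω_h exactly.

Delta peaks are never discretized: they are carried as (position,
strength) pairs and summed analytically in every kernel, so the discrete
path and the spectral path agree to rounding (≤1e-10 asserted).

Cross-channel magnitude checks: the delta components originate from a
single mode and must saturate s_F² = s_h·s_D (enforced at construction);
the Ohmic cross amplitude obeys |η_F| ≤ η_D/2; constructed triples are
additionally checked against the pointwise Cauchy–Schwarz bound
|J_F| ≤ √(J·J_D), which any microscopic mode set satisfies automatically.

## Closed forms and thermal sums

For the Ohmic parts, expanding coth(βE/2) = 1 + 2Σ_{n≥1}e^{−nβE} gives
elementary integrals in τ_n = ω_c t/(1+nθ), θ = βħω_c:

    Re g_l = η [ ln(1+τ_0²)/2 + Σ_{n≥1} ln(1+τ_n²) ]
    Im g_l = η arctan(ω_c t)
    Re D_l/ħ² = η_D ω_c² [ (1−τ_0²)/(1+τ_0²)² + 2Σ (1−τ_n²)/((1+nθ)²(1+τ_n²)²) ]
    Im D_l/ħ² = −2 η_D ω_c² τ_0/(1+τ_0²)²
    Re F_l/ħ = −η_F ω_c τ_0/(1+τ_0²)
    Im F_l/ħ = η_F ω_c [ τ_0²/(1+τ_0²) + 2Σ τ_n²/((1+nθ)(1+τ_n²)) ]

The thermal sums are evaluated with N explicit terms plus the closed-form
midpoint (Euler–Maclaurin) continuation of the summand from n = N + 1/2,
using the exact antiderivatives in τ (for g this brings in the arctangent
integral).  The default N = 1000 leaves a ~1e-10 relative residual at
θ = 1.  `use_eq39_approx=True` selects N = 2 with the continuation from
n = 5/2 — a classical interpolation approximation whose error at θ = 1 is
about 0.2% for g and under 2% across kernels (asserted in tests); it is
exact as θ → 0.  The exact-sum path is always the default and the ground
truth.

## Quadrature over continuous densities

Continuum contributions to g, F, D are integrated on composite 16-point
Gauss–Legendre panels over [0, E_cut], with the node count set to ~20
nodes per cycle of the fastest oscillation cos(E t_max/ħ) (14/cycle for
Brownian-oscillator baths; panel error ~1e-8 there).  For the Ohmic family
E_cut = 45 ħω_c.  For Brownian-oscillator (BO) baths
E_cut = 2.2·max(ω_j) + 20γ, and the [E_cut, ∞) remainder is integrated
analytically using the two-term large-E asymptotics
J_X ≈ C₁/E³ + C₂/E⁵ of the BO lineshape with coth ≈ 1 (valid since
βE_cut ≫ 1), via sine/cosine-integral recurrences.  This keeps the weak
direct one-phonon channel at electronic-gap frequencies — a percent-level
contributor to broadened-bath rates — analytic rather than noisy.

The BO lineshape that replaces each delta under environmental friction γ,

    L(ω; ω_j, γ) = A_j γω / [ (ω² − ω_j²)² + γ²ω² ],

is normalized to unit area on [0, ∞) with A_j in closed form (u = ω²
substitution; separate underdamped, overdamped and critical branches), is
linear as ω → 0⁺ and decays as ω⁻³ — so all three kernels stay integrable
without any window function.

Because g, F, D are band-limited by the bath's spectral support while the
rate integral must resolve the gap phase, kernels may be evaluated on a
coarser grid and cubic-spline resampled (`resample`) onto the rate grid;
the spline error is (ω_max·dt_coarse)⁴/384 relative to the fastest
component.  The surrogate pipeline uses dt_coarse = 2.5e-4 ps against a
rate grid of 9e-5 ps, good to ~3e-4 on the broadened-bath rates.

## Rate integration and diagnostics

One-sided trapezoidal integration of e^{iΔEt/ħ}C(t) on the uniform grid,
reported after Richardson extrapolation against the 2·dt subsample (the
|fine − coarse|/3 difference is kept as `richardson_err`).  Diagnostics:
`integrand_tail`, the end-of-grid magnitude of the damped envelope relative
to its maximum (tolerance 1e-6); and `imag_residual`, the imaginary part of
the two-sided integral reconstructed from the negative-time symmetry rules,
relative to |k| — a consistency check of those rules.  Halving dt or
doubling t_max moves converged rates by well under 0.1%.

Purely discrete baths give a recurrent integrand with no well-defined
rate; `rate` refuses them unless the bath is damped (Ohmic continuum or BO
broadening) or the caller explicitly requests the non-physical Gaussian
apodization flag.  Zero and negative gaps are computed but flagged: the
quasi-adiabatic premise is doubtful there.

## Synthetic inputs and what they show

The six named cases are the reduced-unit parameter sets (θ = 1, η = 1) of
the model study; their values are fixed, including s_F = +√(s_h·s_D) for
case II-A where only the magnitude is determined and the sign is immaterial
(η_F = 0).

The azulene-like surrogate is a deterministic synthetic 48-mode set built
to match reported qualitative features of the S₁ → S₀ transition: a single
dominant NDC projection at 1924 cm⁻¹, Huang–Rhys weight (λ ≈ 1850 cm⁻¹)
concentrated below 1650 cm⁻¹ with a ring-stretch emphasis, and a weakly
coupled CH-stretch block near 3100 cm⁻¹.  The overall NDC scale is a fixed
package constant chosen so the rates over the 1.7816–1.8176 eV gap window
at 300 K land around the 0.1–10 ns⁻¹ decade where the convergence
diagnostics are comfortable.  Because the real per-mode couplings are not
published, only trends across the five bath settings (near-isolated A, B
versus environment-broadened C, D, E) are meaningful; absolute rates are
not claims about azulene.  Integration windows per setting (2 ps; 8 ps for
the weakly damped setting B) are set by where exp(−Re g) falls below 1e-6
of its envelope maximum.

Equally, passing tests on these fixtures shows the machinery is exact for
displaced harmonic baths; it says nothing about anharmonicity, Duschinsky
mixing, or non-Condon effects beyond the momentum coupling, all of which
are out of scope.

## Numerical edge cases

Kernel integrands at E → 0 are finite (the 1/E² and coth divergences cancel
against 1 − cos); Gauss–Legendre nodes never sit at E = 0.  The vibrational
progression makes single-gap comparisons between cases oscillate with the
progression phase, so ordering statements (I-A > I-B > I-C; J_F mattering
less than J_D) are evaluated as averages over one ω_h period at large gap.
Mode sets may be empty (zero kernels, with a warning).  t = 0 rows of the
analytic BO tails use the τ → 0 limits explicitly.
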