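# ndcrate

Fermi's-golden-rule rates for nonadiabatic transitions driven by
**derivative couplings**, including the non-Condon contributions of the
nuclear momentum operator — for photophysicists and theoretical chemists
computing nonradiative decay (internal conversion) rates of molecules in
condensed-phase or isolated environments.

## The model

Two adiabatic electronic states, 1 and 2, are coupled by the first
nonadiabatic derivative coupling (NDC), which multiplies the nuclear
momentum.  All nuclear and environmental degrees of freedom are displaced
harmonic oscillators.  The microscopic input per mode j is the frequency
ω_j, the dimensionless vibronic coupling g_j (Huang–Rhys factor S_j = g_j²)
and the dimensionless NDC projection f_j.  Three bath spectral densities
summarize them,

    J(ω)   = Σ_j ω_j² g_j²     δ(ω − ω_j)        (Franck–Condon)
    J_D(ω) = Σ_j ω_j² f_j²     δ(ω − ω_j)        (squared NDC)
    J_F(ω) = Σ_j ω_j² g_j f_j  δ(ω − ω_j)        (cross, signed)

and determine three time kernels: the lineshape exponent g(t), the NDC
autocorrelation D(t), and the cross kernel F(t).  The rate at adiabatic
energy gap ΔE = E₁ − E₂ is

    k = (2/ħ²) Re ∫₀^∞ dt  e^{iΔE t/ħ}  e^{−g(t)}  [ D(t) − F(t)² ] ,

with the Condon reference obtained by freezing D at D(0).  The
Ohmic-plus-delta family J(ω) = η ħω e^{−ω/ω_c} + s_h ħ²ω_h² δ(ħω − ħω_h)
(and its J_D, J_F analogues with η_D, s_D, η_F, s_F) has closed-form
kernels; arbitrary discrete mode sets are summed exactly, and each mode can
be broadened into a normalized Brownian-oscillator lineshape with friction
γ.  Everything runs in physical units (cm⁻¹, ps, K) or the reduced units
k_B = ħ = ω_c = 1.

## Worked example

`examples/model_case_rates.py` computes the full and Condon rates for the
named reduced-unit case I-A (vibration at ω_h = 5ω_c carrying all the NDC
weight, θ = βħω_c = 1):

```
case I-A (omega_h = 5 omega_c, NDC carried entirely by the vibration)
 gap    k (full)    k (Condon)   ratio
   5   3.9119e+00   6.1456e+01    0.06
  10   2.8778e+01   3.2459e+01    0.89
  15   4.0047e+01   1.1417e+01    3.51
  20   2.3897e+01   3.0080e+00    7.94
  25   8.9982e+00   6.3316e-01   14.21
  30   2.4759e+00   1.1093e-01   22.32
```

Rates are in units of ω_c.  The growing full/Condon ratio is the
non-Condon momentum effect: the time dependence of D(t) lets the
high-frequency vibration absorb an extra quantum, which matters more the
deeper the transition sits in the energy-gap-law tail.  The other examples
build spectral densities (`spectral_densities.py`), run the azulene-like
surrogate under five environmental settings (`azulene_surrogate_scan.py`),
and process a user mode table with Brownian-oscillator broadening
(`custom_modes.py`).

A thin CLI wraps the same library:

```
ndcrate scan --case I-A --theta 1 --dt 0.01 --t-max 40 \
             --gap-min 10 --gap-max 30 --gap-n 21 -o scan.csv
ndcrate fixtures --what surrogate -o azulene_like_modes.csv
```

## Scope

Displaced oscillators only (no Duschinsky rotation or frequency changes),
golden-rule order only, and no spectra beyond what g(t) would support.  The
azulene-like mode set is a synthetic surrogate for trend studies, not the
molecule's ab initio data.
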