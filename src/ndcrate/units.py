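"""Unit systems and thermodynamic state.

Two unit systems are supported:

* **physical** — energies (and spectroscopic frequencies) in cm^-1, times in
  ps, temperatures in kelvin.  ħ and k_B are fixed conversion constants in
  these units; rates come out in ps^-1.
* **reduced** — k_B = ħ = 1 and the Ohmic cutoff ω_c is the unit of energy
  and frequency, so the single thermal parameter is θ = βħω_c = 1/T.

Everywhere in this package a "frequency" ω is carried as the mode energy
ħω in the active energy unit; the angular frequency entering oscillatory
kernels is obtained as E/ħ.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA-level constants in spectroscopic units
HBAR_CM_PS = 5.308837458876146  # ħ in cm^-1 * ps  (= 1e12 / (2*pi*c[cm/s]))
KB_CM_K = 0.695034800  # k_B in cm^-1 / K
EV_TO_CM = 8065.543937  # 1 eV in cm^-1
CM_TO_NS = 1.0e3  # ps^-1 -> ns^-1 factor applies to rates, kept for clarity


@dataclass(frozen=True)
class UnitSystem:
    """Fixed constants of the active unit system."""

    name: str
    hbar: float  # energy * time
    kB: float  # energy / temperature

    @property
    def reduced(self) -> bool:
        return self.name == "reduced"


PHYSICAL = UnitSystem("physical", HBAR_CM_PS, KB_CM_K)
REDUCED = UnitSystem("reduced", 1.0, 1.0)


def unit_system(name: str) -> UnitSystem:
    try:
        return {"physical": PHYSICAL, "reduced": REDUCED}[name]
    except KeyError:  # pragma: no cover - trivial guard
        raise ValueError(f"unknown unit system {name!r}; use 'physical' or 'reduced'")


@dataclass(frozen=True)
class ThermoState:
    """Temperature of the initial-state bath.

    Parameters
    ----------
    temperature:
        Kelvin in the physical system; in reduced units the temperature in
        units of ħω_c/k_B, i.e. ``temperature = 1/θ``.
    units:
        The :class:`UnitSystem` the temperature refers to.
    """

    temperature: float
    units: UnitSystem = PHYSICAL

    def __post_init__(self) -> None:
        if not (self.temperature > 0.0):
            raise ValueError("temperature must be > 0")

    @property
    def beta(self) -> float:
        """Inverse energy 1/(k_B T) in the active unit system."""
        return 1.0 / (self.units.kB * self.temperature)

    def theta(self, cutoff_energy: float) -> float:
        """Dimensionless thermal parameter θ = β·ħω_c for a cutoff energy."""
        return self.beta * cutoff_energy

    @classmethod
    def from_theta(cls, theta: float) -> "ThermoState":
        """Reduced-unit state from θ = βħω_c (with ω_c = 1)."""
        if not (theta > 0.0):
            raise ValueError("theta must be > 0")
        return cls(temperature=1.0 / theta, units=REDUCED)
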