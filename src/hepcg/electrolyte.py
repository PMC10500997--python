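"""Debye–Hückel utilities: ionic strength ↔ screening length.

The simulation parameter ``kappa`` (Å⁻¹) is the inverse Debye screening
length entering the ``exp(-kappa*r)`` factors of the charge-sourced energy
terms.  The converter below evaluates the monovalent-electrolyte Debye
length from physical constants; because the solvent is implicit, it is a
documented convenience for orienting κ values against salt concentrations,
not a calibration claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

from .errors import ParameterError

__all__ = ["ElectrolyteSpec", "debye_length", "kappa_from_ionic_strength", "kappa_grid"]


@dataclass
class ElectrolyteSpec:
    """Monovalent electrolyte state."""

    ionic_strength: float            # mol/L
    temperature: float = 300.0       # K
    relative_permittivity: float = 78.5

    def __post_init__(self):
        if self.ionic_strength <= 0:
            raise ParameterError(f"ionic strength must be > 0, got {self.ionic_strength}")
        if self.temperature <= 0:
            raise ParameterError(f"temperature must be > 0, got {self.temperature}")
        if self.relative_permittivity <= 0:
            raise ParameterError("relative permittivity must be > 0")


def debye_length(spec: ElectrolyteSpec) -> float:
    """Debye–Hückel screening length κ⁻¹ in Å for monovalent ions.

    κ⁻¹ = sqrt(ε_r ε₀ k_B T / (2 N_A e² I)), with I converted to mol/m³.
    Scales as 1/sqrt(I): doubling the ionic strength divides κ⁻¹ by √2.
    """
    i_si = spec.ionic_strength * 1000.0  # mol/L -> mol/m^3
    lam = np.sqrt(
        spec.relative_permittivity
        * constants.epsilon_0
        * constants.k
        * spec.temperature
        / (2.0 * constants.N_A * constants.e**2 * i_si)
    )
    return float(lam * 1e10)


def kappa_from_ionic_strength(spec: ElectrolyteSpec) -> float:
    """Inverse screening length κ in Å⁻¹ (reciprocal of :func:`debye_length`)."""
    return 1.0 / debye_length(spec)


def kappa_grid() -> list:
    """The calibration κ grid: exactly 0.0, 0.1, …, 1.0 (11 values).

    Generated decimal-safely (each value is the canonical float of i/10, no
    accumulated floating-point error), so the values are usable as keys.
    """
    return [i / 10 for i in range(11)]
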