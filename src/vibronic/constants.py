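"""Physical constants and unit conversions.

Internal unit system (single source of truth for the whole package):

* masses        — atomic mass units (amu)
* lengths       — Angstrom
* frequencies   — wavenumbers (cm^-1)
* energies      — electronvolt (eV)
* normal-mode displacements DeltaQ — amu^(1/2) * Angstrom

The Huang-Rhys factor of a mode with wavenumber ``omega`` (cm^-1) and
mass-weighted displacement ``dq`` (amu^1/2 Angstrom) is

    S = omega_angular * dq_SI^2 / (2 hbar)
      = [pi c amu 1e-20 / hbar] * omega * dq^2

so the bracketed coefficient is precomputed once here; every conversion in
the package goes through this module to avoid silent unit bugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA-derived constants in the units the package uses internally."""

    #: reduced Planck constant, J s (exactly h/2pi with h the SI-defined value)
    hbar: float = 6.62607015e-34 / (2.0 * math.pi)
    #: speed of light, cm/s (so that 2*pi*c*omega_cm1 is an angular frequency)
    c: float = 2.99792458e10
    #: kg per atomic mass unit (CODATA 2022)
    amu_to_kg: float = 1.66053906892e-27
    #: eV per cm^-1 (h*c/e)
    wavenumber_to_eV: float = 1.2398419843320026e-4

    def __post_init__(self) -> None:
        for name in ("hbar", "c", "amu_to_kg", "wavenumber_to_eV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name!r} must be strictly positive")
        if abs(self.wavenumber_to_eV - 1.2398419e-4) > 1e-7:
            raise ValueError("wavenumber_to_eV inconsistent with h*c/e")

    @property
    def huang_rhys_coefficient(self) -> float:
        """Coefficient k such that S = k * omega_cm1 * dq^2.

        ``dq`` in amu^1/2 Angstrom.  Equals pi*c*amu*1e-20/hbar
        (the 1e-20 converts Angstrom^2 to m^2).
        """
        return math.pi * self.c * self.amu_to_kg * 1e-20 / self.hbar


#: module-level default constants instance
CONST = PhysicalConstants()
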