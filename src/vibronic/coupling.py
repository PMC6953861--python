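"""Huang-Rhys factors, reorganization-energy partitioning, adiabatic
four-point energies, activation energy and the phonon-number estimate.

The Huang-Rhys factor of mode j,

    S_j = omega_j * DeltaQ_j^2 / (2 hbar),

with omega_j the angular frequency and DeltaQ_j the mass-weighted
normal-mode displacement between the two electronic-state minima, measures
the electron-vibrational coupling strength of that mode.  Its per-mode
reorganization energy is lambda_j = hbar*omega_j*S_j, and on each harmonic
surface these sum to the surface's relaxation energy; the total
intramolecular reorganization energy is lambda_i = lambda_N + lambda_C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import CONST, PhysicalConstants
from .models import StateHarmonicModel, ValidationError, VibronicModeTable
from .projection import normal_mode_displacements


def huang_rhys(
    frequency: float, delta_q: float, *, const: PhysicalConstants = CONST
) -> float:
    """Huang-Rhys factor S from wavenumber (cm^-1) and displacement
    (amu^1/2 Angstrom)."""
    if frequency <= 0:
        raise ValidationError(f"frequency must be positive, got {frequency}")
    return const.huang_rhys_coefficient * frequency * float(delta_q) ** 2


def delta_q_from_huang_rhys(
    frequency: float, s: float, *, const: PhysicalConstants = CONST
) -> float:
    """|DeltaQ| (amu^1/2 Angstrom) that yields Huang-Rhys factor ``s`` at
    wavenumber ``frequency`` — the algebraic inverse of :func:`huang_rhys`."""
    if frequency <= 0:
        raise ValidationError(f"frequency must be positive, got {frequency}")
    if s < 0:
        raise ValidationError(f"Huang-Rhys factor must be >= 0, got {s}")
    return math.sqrt(s / (const.huang_rhys_coefficient * frequency))


def mode_reorg_energy(
    frequency: float, s: float, *, const: PhysicalConstants = CONST
) -> float:
    """Per-mode reorganization energy lambda_j = hbar*omega_j*S_j (eV)."""
    if frequency <= 0:
        raise ValidationError(f"frequency must be positive, got {frequency}")
    if s < 0:
        raise ValidationError(f"Huang-Rhys factor must be >= 0, got {s}")
    return const.wavenumber_to_eV * frequency * s


@dataclass(frozen=True)
class ReorgSummary:
    """Reorganization-energy partition of a state pair."""

    lambda_n: float  # neutral-surface relaxation energy, eV
    lambda_c: float  # charged-surface relaxation energy, eV
    per_mode_neutral: VibronicModeTable | None = None
    per_mode_charged: VibronicModeTable | None = None

    @property
    def lambda_i(self) -> float:
        """Total intramolecular reorganization energy (eV)."""
        return self.lambda_n + self.lambda_c


def adiabatic_reorg(
    e_n: float, e_n_rel: float, e_c: float, e_c_rel: float
) -> ReorgSummary:
    """Four-point adiabatic reorganization energies.

    ``e_n``/``e_c`` are each surface's energy at its own minimum;
    ``e_n_rel``/``e_c_rel`` the same surface evaluated at the partner
    state's minimum (all eV).  lambda_N = E_N(rel) - E_N,
    lambda_C = E_C(rel) - E_C.
    """
    lam_n = e_n_rel - e_n
    lam_c = e_c_rel - e_c
    if lam_n < 0 or lam_c < 0:
        raise ValidationError(
            f"negative relaxation energy (lambda_N={lam_n:.4g}, "
            f"lambda_C={lam_c:.4g} eV): energies inconsistent with each "
            "surface's minimum being its lowest point"
        )
    return ReorgSummary(lam_n, lam_c)


def activation_energy(
    frequency: float, s: float, upsilon: float, *, const: PhysicalConstants = CONST
) -> float:
    """High-temperature electron-transfer activation energy (eV).

    E_A = hbar*omega*(upsilon - S)^2 / (4 S): parabolic in the phonon count
    upsilon, vanishing at the activationless point upsilon = S.
    """
    if s <= 0:
        raise ValidationError(
            "activation energy is singular at S = 0; need S > 0"
        )
    hw = const.wavenumber_to_eV * frequency
    return hw * (upsilon - s) ** 2 / (4.0 * s)


def phonon_estimate(s: float) -> int:
    """Number of phonons excited by an activationless vibronic transition:
    the nearest integer to S (half-away-from-zero rounding)."""
    if s < 0:
        raise ValidationError(f"Huang-Rhys factor must be >= 0, got {s}")
    return int(math.floor(s + 0.5))


def build_mode_table(
    state_from: StateHarmonicModel,
    state_to: StateHarmonicModel,
    basis: str = "neutral",
    *,
    const: PhysicalConstants = CONST,
) -> VibronicModeTable:
    """Full projection pipeline: align, project, and tabulate per-mode
    (omega, S, lambda) for the chosen basis, sorted by frequency ascending.
    """
    disp = normal_mode_displacements(state_from, state_to, basis)
    basis_state = next(
        s
        for s in (state_from, state_to)
        if (s.state_label == "neutral") == (basis == "neutral")
    )
    omegas = basis_state.frequencies
    s_vals = np.array(
        [huang_rhys(w, dq, const=const) for w, dq in zip(omegas, disp.delta_q)]
    )
    table = VibronicModeTable.from_columns(basis, omegas, s_vals, const=const)
    return table.sorted_by_frequency()


def reorg_summary(
    neutral: StateHarmonicModel,
    charged: StateHarmonicModel,
    *,
    const: PhysicalConstants = CONST,
) -> ReorgSummary:
    """Mode-partitioned reorganization summary for a neutral/charged pair."""
    tab_n = build_mode_table(neutral, charged, "neutral", const=const)
    tab_c = build_mode_table(neutral, charged, "charged", const=const)
    return ReorgSummary(
        tab_n.total_reorg(), tab_c.total_reorg(), tab_n, tab_c
    )
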