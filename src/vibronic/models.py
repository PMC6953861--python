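"""Core molecular data types: atoms, electronic-state harmonic models and
per-mode (frequency, Huang-Rhys) tables.

A :class:`StateHarmonicModel` is the harmonic description of one electronic
state of a molecule — equilibrium Cartesian geometry, harmonic wavenumbers
and the mass-weighted normal-mode matrix L (3n x n_v, orthonormal columns).
A pair of such models (neutral + charged) is the input to every downstream
computation.  A :class:`VibronicModeTable` is the per-mode
(omega, S, lambda, assignment) summary that characterises the
electron-vibrational coupling of one state basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CONST, PhysicalConstants

STATE_LABELS = ("neutral", "anion", "cation")
#: labels that count as the "charged" basis
CHARGED_LABELS = ("anion", "cation")


class ValidationError(ValueError):
    """Raised when a molecular model violates one of its invariants."""


@dataclass(frozen=True)
class AtomSet:
    """Element symbols and per-atom masses (amu)."""

    elements: tuple[str, ...]
    masses: np.ndarray  # (n,), amu

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        if len(self.elements) != self.masses.shape[0]:
            raise ValidationError(
                f"elements ({len(self.elements)}) and masses "
                f"({self.masses.shape[0]}) lengths differ"
            )
        if np.any(self.masses <= 0):
            raise ValidationError("masses: all atomic masses must be positive")

    @property
    def n(self) -> int:
        return len(self.elements)

    def mass_vector_3n(self) -> np.ndarray:
        """Masses repeated over x,y,z per atom — the diagonal of M (3n,)."""
        return np.repeat(self.masses, 3)

    def substitute_isotope(self, index: int, mass: float) -> "AtomSet":
        """Return a copy with atom ``index`` given a new isotopic mass.

        Elements (and hence connectivity) never change under substitution.
        """
        masses = self.masses.copy()
        masses[index] = mass
        return AtomSet(self.elements, masses)


@dataclass(frozen=True)
class StateHarmonicModel:
    """Harmonic model of one electronic state.

    Parameters
    ----------
    state_label : {"neutral", "anion", "cation"}
    charge : int
        Net molecular charge.
    atoms : AtomSet
    geometry : ndarray, shape (3n,)
        Equilibrium Cartesian coordinates (Angstrom), flattened x1,y1,z1,...
    frequencies : ndarray, shape (n_v,)
        Harmonic wavenumbers (cm^-1); all must be real and positive.
    mode_matrix : ndarray, shape (3n, n_v)
        Mass-weighted normal modes, orthonormal columns.
    energy : float, optional
        Adiabatic energy at this state's own minimum (eV).
    energy_at_other_minimum : float, optional
        Energy of this state evaluated at the partner state's minimum (eV).
    linear : bool
        Linear molecules carry 3n-5 modes, nonlinear 3n-6.
    """

    state_label: str
    charge: int
    atoms: AtomSet
    geometry: np.ndarray
    frequencies: np.ndarray
    mode_matrix: np.ndarray
    energy: float | None = None
    energy_at_other_minimum: float | None = None
    linear: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "geometry", np.asarray(self.geometry, float))
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))
        object.__setattr__(self, "mode_matrix", np.asarray(self.mode_matrix, float))
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.state_label not in STATE_LABELS:
            raise ValidationError(
                f"state_label: {self.state_label!r} not one of {STATE_LABELS}"
            )
        n = self.atoms.n
        if self.geometry.shape != (3 * n,):
            raise ValidationError(
                f"geometry: expected shape ({3 * n},), got {self.geometry.shape}"
            )
        expected_nv = 3 * n - 5 if self.linear else 3 * n - 6
        n_v = self.frequencies.shape[0]
        if n_v != expected_nv:
            raise ValidationError(
                f"frequencies: expected n_v={expected_nv} modes for "
                f"{'linear' if self.linear else 'nonlinear'} molecule with "
                f"{n} atoms, got {n_v}"
            )
        if np.any(self.frequencies <= 0):
            raise ValidationError(
                "frequencies: imaginary frequency (non-positive wavenumber) "
                "not allowed in a harmonic minimum model"
            )
        if self.mode_matrix.shape != (3 * n, n_v):
            raise ValidationError(
                f"mode_matrix: expected shape ({3 * n}, {n_v}), "
                f"got {self.mode_matrix.shape}"
            )
        gram = self.mode_matrix.T @ self.mode_matrix
        if not np.allclose(gram, np.eye(n_v), atol=1e-6):
            raise ValidationError(
                "mode_matrix: columns not orthonormal to 1e-6 "
                f"(max deviation {np.abs(gram - np.eye(n_v)).max():.3e})"
            )

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.atoms.n

    @property
    def n_modes(self) -> int:
        return self.frequencies.shape[0]

    @property
    def is_charged(self) -> bool:
        return self.state_label in CHARGED_LABELS

    def coordinates(self) -> np.ndarray:
        """Geometry reshaped to (n, 3)."""
        return self.geometry.reshape(-1, 3)


@dataclass
class ModeRow:
    """One row of a vibronic mode table."""

    omega: float  # cm^-1
    huang_rhys: float  # dimensionless
    reorg: float  # eV
    assignment: str = ""


@dataclass
class VibronicModeTable:
    """Per-mode (omega, S, lambda, assignment) table for one state basis.

    The per-mode reorganization energy obeys lambda_j = hbar*omega_j*S_j,
    i.e. ``wavenumber_to_eV * omega * S`` in package units; rows loaded with
    an inconsistent lambda trigger a warning (external tables are rounded to
    a finite number of digits and occasionally round the last digit the
    other way).
    """

    state_basis: str  # "neutral" or "charged"
    rows: list[ModeRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state_basis not in ("neutral", "charged"):
            raise ValidationError(
                f"state_basis must be 'neutral' or 'charged', got {self.state_basis!r}"
            )
        for row in self.rows:
            if row.huang_rhys < 0:
                raise ValidationError(f"huang_rhys < 0 in row {row}")
            if row.reorg < 0:
                raise ValidationError(f"lambda < 0 in row {row}")

    # ------------------------------------------------------------------
    @classmethod
    def from_columns(
        cls,
        state_basis: str,
        omega,
        huang_rhys,
        reorg=None,
        assignment=None,
        *,
        const: PhysicalConstants = CONST,
        lambda_tolerance: float = 5e-4,
    ) -> "VibronicModeTable":
        """Build a table, recomputing lambda where absent and checking it
        for consistency where given.

        ``lambda_tolerance`` is half a unit in the last printed digit of
        typical three-decimal tables; a mismatch beyond it warns (never
        fails) and the given value is preserved.
        """
        omega = np.asarray(omega, float)
        s = np.asarray(huang_rhys, float)
        if omega.shape != s.shape:
            raise ValidationError("omega and huang_rhys lengths differ")
        if assignment is None:
            assignment = [""] * omega.size
        rows = []
        for i in range(omega.size):
            lam_calc = const.wavenumber_to_eV * omega[i] * s[i]
            if reorg is None or reorg[i] is None or (
                isinstance(reorg[i], float) and np.isnan(reorg[i])
            ):
                lam = lam_calc
            else:
                lam = float(reorg[i])
                if abs(lam - lam_calc) > lambda_tolerance:
                    warnings.warn(
                        f"mode {omega[i]:.0f} cm^-1: given lambda={lam:.4g} eV "
                        f"inconsistent with hbar*omega*S={lam_calc:.4g} eV "
                        "beyond rounding tolerance; keeping the given value",
                        stacklevel=2,
                    )
            rows.append(ModeRow(float(omega[i]), float(s[i]), lam, str(assignment[i])))
        return cls(state_basis, rows)

    # ------------------------------------------------------------------
    @property
    def omegas(self) -> np.ndarray:
        return np.array([r.omega for r in self.rows])

    @property
    def huang_rhys_factors(self) -> np.ndarray:
        return np.array([r.huang_rhys for r in self.rows])

    @property
    def reorg_energies(self) -> np.ndarray:
        return np.array([r.reorg for r in self.rows])

    def total_reorg(self) -> float:
        """Sum of per-mode reorganization energies (eV)."""
        return float(self.reorg_energies.sum())

    def sorted_by_frequency(self) -> "VibronicModeTable":
        rows = sorted(self.rows, key=lambda r: r.omega)
        return VibronicModeTable(self.state_basis, rows)

    def __len__(self) -> int:
        return len(self.rows)
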