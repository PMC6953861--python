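"""Geometry alignment, normal-mode displacement projection and the
Duschinsky rotation matrix.

The displacement between the equilibrium geometries of two electronic
states, expressed in a common frame, is projected onto the mass-weighted
normal modes of one state (the *basis*):

    DeltaQ = L^T M^(1/2) (x_other(0) - x_basis(0))

in amu^(1/2) Angstrom.  Because the two quantum-chemistry geometries carry
an arbitrary relative rotation/translation, the moving geometry is first
superimposed on the basis geometry by mass-weighted Kabsch alignment
(proper rotations only) — the standard Eckart-condition resolution of the
frame ambiguity.  Rectilinear modes only; curvilinear-coordinate
transforms are out of scope.

The Duschinsky matrix J = (L')^T L quantifies how the initial state's
modes mix when expressed in the final state's modes; for orthonormal
rectilinear mode matrices of the same molecule J is orthogonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import StateHarmonicModel, ValidationError


@dataclass(frozen=True)
class DisplacementResult:
    """Normal-mode displacements of one state pair in one basis."""

    basis: str  # "neutral" or "charged"
    delta_q: np.ndarray  # (n_v,), amu^1/2 Angstrom
    aligned_displacement: np.ndarray  # (3n,), Angstrom, in the basis frame
    #: fraction of the mass-weighted displacement outside the mode span
    residual_fraction: float = 0.0


@dataclass(frozen=True)
class DuschinskyResult:
    """Mode-mixing matrix J plus displacement vector in the final basis."""

    j_matrix: np.ndarray  # (n_v, n_v)
    delta_q: np.ndarray  # (n_v,), final-state basis
    #: per-mode largest |J| off-diagonal entry and mixing fraction 1-J_jj^2
    diagnostics: dict


# ----------------------------------------------------------------------
def _kabsch(ref: np.ndarray, mov: np.ndarray, weights: np.ndarray):
    """Weighted Kabsch: rotation R and translation mapping mov onto ref.

    Proper rotations only.  If the reflected (improper) fit is drastically
    better than the best proper rotation — the signature of a mirror-image
    (chirality) mismatch rather than an ordinary geometry distortion —
    raise instead of silently reflecting.
    """
    w = weights / weights.sum()
    c_ref = w @ ref
    c_mov = w @ mov
    a = (ref - c_ref) * w[:, None]
    b = mov - c_mov
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.linalg.det(u @ vt)
    if d < 0:
        # weighted squared residual for the best proper / improper fits
        c2 = float((w[:, None] * ((ref - c_ref) ** 2 + b**2)).sum())
        e2_improper = max(c2 - 2.0 * s.sum(), 0.0)
        e2_proper = max(c2 - 2.0 * (s[0] + s[1] - s[2]), 0.0)
        if e2_improper < 0.25 * e2_proper:
            raise ValidationError(
                "best-fit superposition requires a reflection (chirality "
                "mismatch); proper rotations only"
            )
        u[:, -1] *= -1.0
    rot = u @ vt  # applied as mov_centered @ rot
    return rot, c_ref, c_mov


def align_structures(
    reference: StateHarmonicModel, moving: StateHarmonicModel
) -> np.ndarray:
    """Mass-weighted least-squares superposition of ``moving`` onto
    ``reference``; returns the aligned 3n geometry (Angstrom).

    After alignment the net mass-weighted translation is zero and the
    mass-weighted RMSD is minimal over proper rigid motions.
    """
    if reference.atoms.elements != moving.atoms.elements:
        raise ValidationError(
            "element-order mismatch between the two states; atoms must be "
            "listed in the same order"
        )
    ref = reference.coordinates()
    mov = moving.coordinates()
    rot, c_ref, c_mov = _kabsch(ref, mov, reference.atoms.masses)
    aligned = (mov - c_mov) @ rot + c_ref
    return aligned.reshape(-1)


def rotate_mode_matrix(mode_matrix: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Apply the alignment rotation to every atomic 3-vector block of a
    (3n, n_v) mode matrix.

    Uses the same row-vector convention as the geometry transform
    ``aligned = centered @ rot``, i.e. each block b -> rot^T b.
    """
    n3, n_v = mode_matrix.shape
    blocks = mode_matrix.reshape(-1, 3, n_v)
    return np.einsum("ab,nav->nbv", rot, blocks).reshape(n3, n_v)


def _aligned_pair(basis_state: StateHarmonicModel, other: StateHarmonicModel):
    """Align ``other`` onto ``basis_state``; return (aligned geom, rotation)."""
    if basis_state.atoms.elements != other.atoms.elements:
        raise ValidationError("element-order mismatch between the two states")
    ref = basis_state.coordinates()
    mov = other.coordinates()
    rot, c_ref, c_mov = _kabsch(ref, mov, basis_state.atoms.masses)
    aligned = (mov - c_mov) @ rot + c_ref
    return aligned.reshape(-1), rot


def _select_basis(
    state_from: StateHarmonicModel, state_to: StateHarmonicModel, basis: str
):
    states = {s.state_label: s for s in (state_from, state_to)}
    if basis == "neutral":
        basis_state = states.get("neutral")
    elif basis == "charged":
        charged = [s for s in (state_from, state_to) if s.is_charged]
        basis_state = charged[0] if charged else None
    else:
        raise ValidationError(f"basis must be 'neutral' or 'charged', got {basis!r}")
    if basis_state is None:
        raise ValidationError(f"no state with basis {basis!r} in the pair")
    other = state_to if basis_state is state_from else state_from
    return basis_state, other


def normal_mode_displacements(
    state_from: StateHarmonicModel,
    state_to: StateHarmonicModel,
    basis: str = "neutral",
    *,
    residual_warn_fraction: float = 0.01,
) -> DisplacementResult:
    """Project the inter-state geometry change onto one state's normal modes.

    ``basis`` selects whose mode matrix projects: the neutral-basis
    displacement is L_N^T M^(1/2) (x_C(0) - x_N(0)), the charged-basis one
    L_C^T M^(1/2) (x_N(0) - x_C(0)) — in both conventions "other minus
    basis".  The other state's geometry is Kabsch-aligned onto the basis
    frame first.

    The component of M^(1/2) dx outside the span of the mode matrix
    (rotation/translation contamination or span deficiency) is reported as
    ``residual_fraction`` and warned about above 1% — never silently
    dropped.
    """
    basis_state, other = _select_basis(state_from, state_to, basis)
    if state_from.n_modes != state_to.n_modes:
        raise ValidationError(
            f"mode-count mismatch: {state_from.n_modes} vs {state_to.n_modes}"
        )
    aligned_other, _rot = _aligned_pair(basis_state, other)
    dx = aligned_other - basis_state.geometry
    sqrt_m = np.sqrt(basis_state.atoms.mass_vector_3n())
    mw_dx = sqrt_m * dx
    # explicit sanity check that alignment removed net mass-weighted translation
    net = (basis_state.atoms.masses[:, None] * dx.reshape(-1, 3)).sum(axis=0)
    if np.abs(net).max() / basis_state.atoms.masses.sum() > 1e-8:
        raise ValidationError(
            "unaligned frames: net mass-weighted translation exceeds 1e-8"
        )
    delta_q = basis_state.mode_matrix.T @ mw_dx
    norm = np.linalg.norm(mw_dx)
    # residual fraction is meaningless for a numerically zero displacement
    if norm > 1e-10:
        residual = np.linalg.norm(mw_dx - basis_state.mode_matrix @ delta_q) / norm
    else:
        residual = 0.0
    if residual > residual_warn_fraction:
        warnings.warn(
            f"{residual:.1%} of the mass-weighted displacement lies outside "
            "the normal-mode span (rotation/translation contamination or "
            "missing modes)",
            stacklevel=2,
        )
    return DisplacementResult(basis, delta_q, dx, float(residual))


def duschinsky_matrix(
    state_initial: StateHarmonicModel,
    state_final: StateHarmonicModel,
    *,
    mixing_threshold: float = 0.3,
) -> DuschinskyResult:
    """Duschinsky rotation matrix J = (L')^T L between two states.

    The initial state is aligned onto the final state's frame (its mode
    matrix rotated accordingly) before forming J.  The displacement vector
    is reported in the final-state basis.  Diagnostics list, per final
    mode, the largest off-diagonal |J| entry, the mixing fraction
    1 - J_jj^2, and the modes whose off-diagonal coupling exceeds
    ``mixing_threshold``.
    """
    if state_initial.n_modes != state_final.n_modes:
        raise ValidationError(
            f"unequal mode counts: {state_initial.n_modes} vs {state_final.n_modes}"
        )
    aligned_geom, rot = _aligned_pair(state_final, state_initial)
    l_init = rotate_mode_matrix(state_initial.mode_matrix, rot)
    j = l_init.T @ state_final.mode_matrix
    sqrt_m = np.sqrt(state_final.atoms.mass_vector_3n())
    delta_q = state_final.mode_matrix.T @ (sqrt_m * (aligned_geom - state_final.geometry))
    off = j - np.diag(np.diag(j))
    max_off = np.abs(off).max(axis=0)
    mixing = 1.0 - np.diag(j) ** 2
    diagnostics = {
        "max_offdiagonal": max_off,
        "mixing_fraction": mixing,
        "strongly_mixed_modes": np.nonzero(max_off > mixing_threshold)[0].tolist(),
    }
    return DuschinskyResult(j, delta_q, diagnostics)
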