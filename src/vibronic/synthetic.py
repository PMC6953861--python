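"""Synthetic state-model pairs and mode tables with analytically known
ground truth.

These generators stand in for quantum-chemistry-derived inputs: displaced
harmonic oscillators whose Huang-Rhys factors are known in closed form,
random polyatomics constructed to invert the projection pipeline exactly,
and the published HCN per-mode table.  Every generator is deterministic
given its seed/parameters; there is no global random state.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np

from .constants import CONST
from .coupling import delta_q_from_huang_rhys, huang_rhys
from .models import AtomSet, StateHarmonicModel, VibronicModeTable

_ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


# ----------------------------------------------------------------------
def _transrot_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation subspace (3n x rank)."""
    n = masses.shape[0]
    sm = np.sqrt(masses)
    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = sm
        vecs.append(t.ravel())
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    rel = coords - com
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        vecs.append((np.cross(e, rel) * sm[:, None]).ravel())
    v = np.array(vecs).T
    q, s, _ = np.linalg.svd(v, full_matrices=False)
    rank = int((s > 1e-8 * s[0]).sum())  # linear molecules lose one rotation
    return q[:, :rank]


def vibrational_subspace(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the mass-weighted vibrational subspace — the
    complement of translations and rotations (3n x n_v)."""
    tr = _transrot_basis(coords, masses)
    n3 = 3 * masses.shape[0]
    proj = np.eye(n3) - tr @ tr.T
    u, s, _ = np.linalg.svd(proj)
    n_v = n3 - tr.shape[1]
    return u[:, :n_v]


# ----------------------------------------------------------------------
def make_displaced_diatomic(
    m1: float,
    m2: float,
    frequency: float,
    delta_r: float,
    r0: float = 1.1,
    charged_frequency: float | None = None,
):
    """Diatomic pair whose bond lengths differ by ``delta_r`` (Angstrom).

    Both states share the mass-weighted stretch mode; the exact ground
    truth S = k * omega * mu * delta_r^2 (mu the reduced mass) is returned
    alongside.  ``charged_frequency`` lets isotope/relaxation studies give
    the charged surface its own wavenumber (ground truth always refers to
    the neutral basis).
    """
    if m1 <= 0 or m2 <= 0 or frequency <= 0:
        raise ValueError("masses and frequency must be positive")
    masses = np.array([m1, m2])
    mu = m1 * m2 / (m1 + m2)
    total = m1 + m2
    # mass-weighted stretch mode, COM-preserving, unit norm
    u = np.array([0, 0, -math.sqrt(m1) * m2 / total, 0, 0, math.sqrt(m2) * m1 / total])
    mode = (u / np.linalg.norm(u)).reshape(6, 1)
    geom1 = np.array([0, 0, 0, 0, 0, r0], float)
    # displace along the mode itself so the stretch changes by exactly delta_r
    dq = math.sqrt(mu) * delta_r
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    geom2 = geom1 + inv_sqrt_m * (mode[:, 0] * dq)
    atoms = AtomSet(("X", "Y"), masses)
    neutral = StateHarmonicModel(
        "neutral", 0, atoms, geom1, np.array([frequency]), mode, linear=True
    )
    anion = StateHarmonicModel(
        "anion",
        -1,
        atoms,
        geom2,
        np.array([charged_frequency or frequency]),
        mode,
        linear=True,
    )
    s_expected = huang_rhys(frequency, dq)
    return neutral, anion, s_expected


# ----------------------------------------------------------------------
def make_random_polyatomic(
    n_atoms: int,
    seed: int,
    s_targets,
    frequencies=None,
    apply_random_frame: bool = False,
):
    """Random nonlinear polyatomic pair built to invert the projection
    pipeline: running align -> project -> Huang-Rhys on the pair recovers
    exactly ``s_targets`` (one per mode, frequency-ascending order).

    The mode matrix is a seeded random orthonormal basis of the
    translation/rotation complement, so the constructed displacement is
    contamination-free.  ``apply_random_frame`` additionally subjects the
    charged state to a seeded rigid rotation+translation, exercising the
    alignment step.
    """
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    s_targets = np.asarray(s_targets, float)
    n_v = 3 * n_atoms - 6
    if s_targets.shape[0] != n_v:
        raise ValueError(f"s_targets must have length 3n-6 = {n_v}")
    rng = np.random.default_rng(seed)
    symbols = rng.choice(list(_ELEMENT_MASSES), size=n_atoms)
    masses = np.array([_ELEMENT_MASSES[s] for s in symbols])
    coords = rng.normal(scale=1.5, size=(n_atoms, 3))
    basis = vibrational_subspace(coords, masses)
    mix, _ = np.linalg.qr(rng.normal(size=(n_v, n_v)))
    mode_matrix = basis @ mix
    if frequencies is None:
        frequencies = np.sort(rng.uniform(300.0, 3500.0, size=n_v))
    else:
        frequencies = np.asarray(frequencies, float)
    dq = np.array(
        [delta_q_from_huang_rhys(w, s) for w, s in zip(frequencies, s_targets)]
    )
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    geom1 = coords.ravel()
    geom2 = geom1 + inv_sqrt_m * (mode_matrix @ dq)
    modes2 = mode_matrix
    if apply_random_frame:
        rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1.0
        shift = rng.normal(scale=3.0, size=3)
        geom2 = (geom2.reshape(-1, 3) @ rot + shift).ravel()
        from .projection import rotate_mode_matrix

        modes2 = rotate_mode_matrix(mode_matrix, rot)
    atoms = AtomSet(tuple(symbols), masses)
    neutral = StateHarmonicModel(
        "neutral", 0, atoms, geom1, frequencies, mode_matrix, linear=False
    )
    anion = StateHarmonicModel(
        "anion", -1, atoms, geom2, frequencies.copy(), modes2, linear=False
    )
    return neutral, anion


# ----------------------------------------------------------------------
def make_hcn_like(state_label: str = "neutral"):
    """Linear triatomic H-C-N-like model with 4 modes (degenerate bend pair
    plus two stretches), used as the packaged schema fixture."""
    masses = np.array([1.008, 12.011, 14.007])
    coords = np.array([[0, 0, 0.0], [0, 0, 1.07], [0, 0, 2.22]])
    basis = vibrational_subspace(coords, masses)  # 9 - 5 = 4 columns
    freqs = np.array([778.0, 778.0, 2149.0, 3500.0])
    charge = 0 if state_label == "neutral" else -1
    return StateHarmonicModel(
        state_label,
        charge,
        AtomSet(("H", "C", "N"), masses),
        coords.ravel(),
        freqs,
        basis,
        linear=True,
    )


def packaged_hcn_like_path():
    """Path to the packaged HCN-like synthetic JSON fixture."""
    return resources.files("vibronic").joinpath("data/hcn_like_synthetic.json")


# ----------------------------------------------------------------------
#: HCN per-mode table, published values: (omega cm^-1, S, lambda eV, assignment)
_HCN_NEUTRAL = [
    (778.0, 0.0, 0.0, "bend"),
    (2149.0, 1.978, 0.527, "C#N stretch"),
    (3500.0, 0.084, 0.036, "C-H stretch"),
]
_HCN_ANIONIC = [
    (696.0, 0.0, 0.0, "bend"),
    (1704.0, 1.594, 0.337, "C#N stretch"),
    (3446.0, 0.029, 0.013, "C-H stretch"),
]


def table1_hcn() -> tuple[VibronicModeTable, VibronicModeTable]:
    """The published HCN neutral/anionic per-mode tables.

    Note: the anionic C-H row's printed lambda (0.013 eV) differs from
    hbar*omega*S (0.0124 eV) in the last digit; loading it warns and keeps
    the printed value.
    """
    def build(rows, basis):
        omega, s, lam, assign = zip(*rows)
        return VibronicModeTable.from_columns(basis, omega, s, lam, assign, const=CONST)

    return build(_HCN_NEUTRAL, "neutral"), build(_HCN_ANIONIC, "charged")


# ----------------------------------------------------------------------
#: dominant published emission-band modes of the acetophenone isotopologues.
#: The high-frequency ring C-H stretch band's coupling strength is NOT
#: published; a common nominal S = 0.2 is assigned to both molecules
#: (synthetic stand-in), consistent with the band being reported identical
#: for the pair.
_ACETOPHENONE = [(480.0, 0.177), (1014.0, 0.188), (1630.0, 0.2)]
_ACETOPHENONE_D8 = [(450.0, 0.159), (811.0, 0.21), (1630.0, 0.2)]


def acetophenone_pair_synthetic() -> tuple[VibronicModeTable, VibronicModeTable]:
    """Partial charged-basis mode tables for acetophenone and its fully
    ring/methyl-deuterated isotopologue (synthetic: built from the few
    published dominant modes, not a full normal-mode analysis)."""
    def build(rows):
        omega, s = zip(*rows)
        return VibronicModeTable.from_columns("charged", omega, s)

    return build(_ACETOPHENONE), build(_ACETOPHENONE_D8)
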