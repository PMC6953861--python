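"""Electron-transfer stick spectra, Gaussian convolution, and IETS
intensities.

A stick spectrum places, for every mode j of a (omega, S) table, lines at
E0 + upsilon*omega_j with Poisson weights exp(-S_j) S_j^upsilon / upsilon!
(the mu = 0 Franck-Condon progression; cross-mode combination lines are
not generated), plus a single 0-0 line at E0 weighted by the product of
all the modes' exp(-S_j).  Convolution with a unit-area Gaussian of
standard deviation sigma (default 100 cm^-1, roughly a quarter of the
~400 cm^-1 resolution attributed to biological electron-tunneling
spectrometers) turns the sticks into a smooth comparable curve.

State conventions: an ET *absorption* spectrum (molecule captures the
electron) is built from the NEUTRAL-basis table, an ET *emission* spectrum
(molecule releases it, relaxing from charged to neutral geometry) from the
CHARGED-basis table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coupling import build_mode_table
from .franck_condon import fcf_poisson
from .models import StateHarmonicModel, ValidationError, VibronicModeTable


@dataclass(frozen=True)
class StickSpectrum:
    """Vibronic line positions and weights before broadening."""

    positions: np.ndarray  # cm^-1
    weights: np.ndarray
    mode_index: np.ndarray  # -1 marks the 0-0 line
    upsilon: np.ndarray
    basis: str | None = None
    transition: str | None = None  # "absorption" | "emission"
    e0: float = 0.0


@dataclass(frozen=True)
class ConvolvedSpectrum:
    """Gaussian-broadened spectrum on a wavenumber grid."""

    grid: np.ndarray  # cm^-1, monotone increasing
    values: np.ndarray
    sigma: float
    normalization: str = "none"  # "max1" | "area1" | "none"
    basis: str | None = None
    transition: str | None = None

    def argmax_position(self) -> float:
        """Wavenumber of the global intensity maximum."""
        return float(self.grid[int(np.argmax(self.values))])


@dataclass(frozen=True)
class IETSSpectrum:
    """Per-mode inelastic electron tunneling intensities."""

    frequencies: np.ndarray  # cm^-1 (may be empty if unknown)
    intensities: np.ndarray
    charges: np.ndarray = field(default_factory=lambda: np.empty(0))


# ----------------------------------------------------------------------
def stick_spectrum(
    table: VibronicModeTable,
    upsilon_max: int = 10,
    e0: float = 0.0,
    mode: str = "progression",
    transition: str | None = None,
) -> StickSpectrum:
    """Build the vibronic stick spectrum of a mode table.

    ``mode="progression"`` lays down the full Poisson ladder
    upsilon = 1..upsilon_max per vibrational mode; ``mode="fundamentals"``
    keeps upsilon = 1 only.  Both include the common 0-0 line at ``e0``
    with weight prod_j exp(-S_j).
    """
    if len(table) == 0:
        raise ValidationError("empty mode table")
    if upsilon_max < 1:
        raise ValidationError("upsilon_max must be >= 1")
    if mode not in ("progression", "fundamentals"):
        raise ValidationError(f"unknown stick mode {mode!r}")
    positions = [e0]
    weights = [float(np.exp(-table.huang_rhys_factors).prod())]
    mode_index = [-1]
    upsilons = [0]
    u_top = upsilon_max if mode == "progression" else 1
    for j, row in enumerate(table.rows):
        if row.huang_rhys == 0:
            continue
        for u in range(1, u_top + 1):
            positions.append(e0 + u * row.omega)
            weights.append(fcf_poisson(row.huang_rhys, u))
            mode_index.append(j)
            upsilons.append(u)
    return StickSpectrum(
        np.array(positions),
        np.array(weights),
        np.array(mode_index),
        np.array(upsilons),
        basis=table.state_basis,
        transition=transition,
        e0=e0,
    )


def convolve(
    sticks: StickSpectrum,
    sigma: float = 100.0,
    grid_start: float = 0.0,
    grid_stop: float = 4000.0,
    grid_step: float = 1.0,
    normalization: str = "max1",
) -> ConvolvedSpectrum:
    """Convolve a stick spectrum with a unit-area Gaussian of s.d. ``sigma``.

    The kernel is unit-area (not unit-height) so stick weights remain
    comparable across linewidths; normalization is applied after the sum.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if grid_step <= 0:
        raise ValidationError("grid_step must be positive")
    if grid_step > sigma:
        warnings.warn(
            f"grid step {grid_step} exceeds sigma {sigma}: peaks may be missed",
            stacklevel=2,
        )
    grid = np.arange(grid_start, grid_stop + 0.5 * grid_step, grid_step)
    values = np.zeros_like(grid)
    amp = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for pos, w in zip(sticks.positions, sticks.weights):
        values += w * amp * np.exp(-0.5 * ((grid - pos) / sigma) ** 2)
    values = _normalize(values, grid, normalization)
    return ConvolvedSpectrum(
        grid, values, sigma, normalization, sticks.basis, sticks.transition
    )


def _normalize(values: np.ndarray, grid: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "none":
        return values
    if normalization == "max1":
        peak = values.max()
        return values / peak if peak > 0 else values
    if normalization == "area1":
        area = np.trapezoid(values, grid)
        return values / area if area > 0 else values
    raise ValidationError(f"unknown normalization {normalization!r}")


# ----------------------------------------------------------------------
def _table_from_source(source, basis: str) -> VibronicModeTable:
    if isinstance(source, VibronicModeTable):
        if source.state_basis != basis:
            warnings.warn(
                f"table basis {source.state_basis!r} differs from the "
                f"{basis!r} convention of this transition",
                stacklevel=3,
            )
        return source
    neutral, charged = source
    return build_mode_table(neutral, charged, basis)


def absorption_spectrum(
    source,
    upsilon_max: int = 10,
    e0: float = 0.0,
    sigma: float = 100.0,
    grid=(0.0, 4000.0, 1.0),
    mode: str = "progression",
    normalization: str = "max1",
) -> ConvolvedSpectrum:
    """ET absorption spectrum: neutral-basis (omega, S) progression.

    ``source`` is either a neutral-basis :class:`VibronicModeTable` or a
    (neutral, charged) pair of state models.
    """
    table = _table_from_source(source, "neutral")
    sticks = stick_spectrum(table, upsilon_max, e0, mode, transition="absorption")
    return convolve(sticks, sigma, *grid, normalization=normalization)


def emission_spectrum(
    source,
    upsilon_max: int = 10,
    e0: float = 0.0,
    sigma: float = 100.0,
    grid=(0.0, 4000.0, 1.0),
    mode: str = "progression",
    normalization: str = "max1",
) -> ConvolvedSpectrum:
    """ET emission spectrum: charged-basis (omega, S) progression — the
    odorant relaxing from its charged to its neutral geometry."""
    table = _table_from_source(source, "charged")
    sticks = stick_spectrum(table, upsilon_max, e0, mode, transition="emission")
    return convolve(sticks, sigma, *grid, normalization=normalization)


# ----------------------------------------------------------------------
def iets_intensity(
    charges,
    mode_cartesian_displacements,
    frequencies=None,
) -> IETSSpectrum:
    """Inelastic electron tunneling intensity per mode.

    I_j = sum_i q_i^2 |dx_{i,j}|^2 over atoms i, with q_i the partial
    charge of atom i and dx_{i,j} its Cartesian displacement 3-vector in
    mode j.  ``mode_cartesian_displacements`` is (n_modes, 3n) or a list
    of 3n vectors.
    """
    q = np.asarray(charges, float)
    disp = np.atleast_2d(np.asarray(mode_cartesian_displacements, float))
    n = q.shape[0]
    if disp.shape[1] != 3 * n:
        raise ValidationError(
            f"mode displacement length {disp.shape[1]} does not match "
            f"3 x {n} atoms"
        )
    per_atom_sq = (disp.reshape(disp.shape[0], n, 3) ** 2).sum(axis=2)
    intensities = per_atom_sq @ (q**2)
    freqs = (
        np.asarray(frequencies, float) if frequencies is not None else np.empty(0)
    )
    return IETSSpectrum(freqs, intensities, q)
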