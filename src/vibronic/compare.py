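"""Peak detection, windowed band overlap and whole-spectrum similarity
between convolved spectra — the quantitative odor-character comparison.

The band-overlap metric is the overlapping coefficient: both spectra are
area-normalized over the comparison window and the integral of their
pointwise minimum is taken, giving a bounded shape-based fraction — 1 for
identical band shapes, 0 for disjoint support, symmetric and invariant to
overall intensity scaling.  Cosine similarity over the full grid is
offered as a second, window-free opinion.  Neither metric claims to equal
perceptual odor similarity; the module reports numbers only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .models import ValidationError
from .spectra import ConvolvedSpectrum


@dataclass(frozen=True)
class Peak:
    position: float  # cm^-1
    height: float
    prominence: float


@dataclass(frozen=True)
class PeakList:
    peaks: tuple  # of Peak, sorted by position

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class OverlapReport:
    """Windowed band overlap + whole-grid similarity between two spectra."""

    window: tuple
    overlap_coefficient: float
    cosine_similarity: float
    peak_matches: tuple  # of (pos_a, pos_b_nearest, distance)


# ----------------------------------------------------------------------
def find_peaks(
    spectrum: ConvolvedSpectrum, min_prominence: float = 0.05
) -> PeakList:
    """Local maxima with prominence >= ``min_prominence`` of the global max."""
    values = np.asarray(spectrum.values, float)
    if values.size == 0:
        raise ValidationError("empty spectrum")
    top = values.max()
    if top <= 0:
        return PeakList(())
    idx, props = _scipy_find_peaks(values, prominence=min_prominence * top)
    peaks = tuple(
        Peak(float(spectrum.grid[i]), float(values[i]), float(p))
        for i, p in sorted(zip(idx, props["prominences"]))
    )
    return PeakList(peaks)


def _common_window(a: ConvolvedSpectrum, b: ConvolvedSpectrum, window):
    """Resample both spectra onto the coarser grid restricted to the window."""
    step = max(
        float(np.diff(a.grid).min()), float(np.diff(b.grid).min())
    )
    lo, hi = window
    lo = max(lo, float(a.grid[0]), float(b.grid[0]))
    hi = min(hi, float(a.grid[-1]), float(b.grid[-1]))
    if hi <= lo:
        raise ValidationError(f"empty comparison window ({lo}, {hi})")
    grid = np.arange(lo, hi + 0.5 * step, step)
    ya = np.interp(grid, a.grid, a.values)
    yb = np.interp(grid, b.grid, b.values)
    return grid, ya, yb


def band_overlap(
    a: ConvolvedSpectrum, b: ConvolvedSpectrum, window=None
) -> float:
    """Overlapping coefficient of two spectra over a wavenumber window.

    Each spectrum is area-normalized over the window before taking
    integral(min); the result is in [0, 1], symmetric, and invariant to
    positive scaling of either input.  A window with zero total intensity
    in either spectrum yields 0 with a warning.
    """
    if window is None:
        window = (
            max(float(a.grid[0]), float(b.grid[0])),
            min(float(a.grid[-1]), float(b.grid[-1])),
        )
    grid, ya, yb = _common_window(a, b, window)
    area_a = np.trapezoid(ya, grid)
    area_b = np.trapezoid(yb, grid)
    if area_a <= 0 or area_b <= 0:
        warnings.warn(
            "zero total intensity inside the comparison window; overlap "
            "defined as 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.trapezoid(np.minimum(ya / area_a, yb / area_b), grid))


def spectrum_similarity(a: ConvolvedSpectrum, b: ConvolvedSpectrum) -> float:
    """Cosine similarity over the common grid; in [0, 1] for non-negative
    spectra and invariant to positive scaling."""
    window = (
        max(float(a.grid[0]), float(b.grid[0])),
        min(float(a.grid[-1]), float(b.grid[-1])),
    )
    grid, ya, yb = _common_window(a, b, window)
    na = np.linalg.norm(ya)
    nb = np.linalg.norm(yb)
    if na == 0 or nb == 0:
        raise ValidationError("zero-norm spectrum in similarity computation")
    return float(ya @ yb / (na * nb))


def match_peaks(
    a: PeakList, b: PeakList, tolerance: float = 250.0
) -> tuple:
    """For every peak of ``a``, the nearest peak of ``b`` and its distance.

    The default 250 cm^-1 tolerance (used by callers to decide whether a
    partner exists) is about half the ~400 cm^-1 resolution attributed to
    the biological detector.
    """
    if len(b) == 0:
        return tuple((p.position, None, np.inf) for p in a.peaks)
    pos_b = b.positions
    out = []
    for p in a.peaks:
        k = int(np.argmin(np.abs(pos_b - p.position)))
        out.append((p.position, float(pos_b[k]), float(abs(pos_b[k] - p.position))))
    return tuple(out)


def compare_spectra(
    a: ConvolvedSpectrum,
    b: ConvolvedSpectrum,
    window=None,
    min_prominence: float = 0.05,
    match_tolerance: float = 250.0,
) -> OverlapReport:
    """Full comparison: windowed overlap, cosine similarity, peak matching."""
    ovl = band_overlap(a, b, window)
    cos = spectrum_similarity(a, b)
    matches = match_peaks(
        find_peaks(a, min_prominence), find_peaks(b, min_prominence), match_tolerance
    )
    if window is None:
        window = (
            max(float(a.grid[0]), float(b.grid[0])),
            min(float(a.grid[-1]), float(b.grid[-1])),
        )
    return OverlapReport(tuple(window), ovl, cos, matches)
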