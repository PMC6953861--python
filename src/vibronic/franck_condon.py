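"""Franck-Condon factors for a displaced harmonic oscillator.

The squared overlap of vibrational levels mu (initial state) and upsilon
(final state) of two harmonic surfaces with equal frequency, displaced by
the dimensionless d = sqrt(2 S), has the closed form (upsilon >= mu)

    FCF(mu, upsilon) = exp(-S) S^(upsilon-mu) (mu!/upsilon!)
                       [L_mu^(upsilon-mu)(S)]^2

with L the generalized Laguerre polynomial; for mu = 0 it reduces to the
Poisson distribution exp(-S) S^upsilon / upsilon!.  For upsilon < mu the
indices are swapped (|<chi_mu|chi_upsilon>|^2 is symmetric).  Duschinsky
mixing is neglected here (J = 1): the multimode spectrum is a product of
these one-dimensional factors.

:func:`fcf_oracle` evaluates the same overlap by direct numerical
quadrature of Hermite-function wavefunctions and serves as an independent
correctness check on the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import eval_genlaguerre, eval_hermite, gammaln

from .models import ValidationError


def _check_quanta(*ns: int) -> None:
    for n in ns:
        if n < 0 or int(n) != n:
            raise ValidationError(f"vibrational quantum number must be a non-negative integer, got {n}")


def fcf_poisson(s: float, upsilon: int) -> float:
    """FCF for the 0 -> upsilon transition: exp(-S) S^u / u!."""
    if s < 0:
        raise ValidationError(f"Huang-Rhys factor must be >= 0, got {s}")
    _check_quanta(upsilon)
    if s == 0:
        return 1.0 if upsilon == 0 else 0.0
    return math.exp(-s + upsilon * math.log(s) - gammaln(upsilon + 1))


def fcf_general(s: float, mu: int, upsilon: int) -> float:
    """FCF for the mu -> upsilon transition of a displaced oscillator.

    Factorial ratios go through log-gamma so large quantum numbers do not
    overflow.
    """
    if s < 0:
        raise ValidationError(f"Huang-Rhys factor must be >= 0, got {s}")
    _check_quanta(mu, upsilon)
    if upsilon < mu:
        mu, upsilon = upsilon, mu
    d = upsilon - mu
    if s == 0:
        return 1.0 if d == 0 else 0.0
    log_pref = -s + d * math.log(s) + gammaln(mu + 1) - gammaln(upsilon + 1)
    lag = eval_genlaguerre(mu, d, s)
    return math.exp(log_pref) * float(lag) ** 2


def _hermite_function(n: int, q: np.ndarray) -> np.ndarray:
    """Normalized harmonic-oscillator eigenfunction in dimensionless q."""
    log_norm = -0.5 * (n * math.log(2.0) + gammaln(n + 1)) - 0.25 * math.log(math.pi)
    return math.exp(log_norm) * eval_hermite(n, q) * np.exp(-0.5 * q * q)


def fcf_oracle(
    s: float, mu: int, upsilon: int, *, n_points: int = 4001, rtol: float = 1e-9
) -> float:
    """FCF by numeric quadrature of |<chi_mu(q-d)|chi_upsilon(q)>|^2 with
    d = sqrt(2 S); independent of the closed forms above.

    Integration range +-(12+d); convergence is checked by halving the grid
    and raising if the two estimates disagree beyond ``rtol`` (absolute
    floor 1e-12).
    """
    if s < 0:
        raise ValidationError(f"Huang-Rhys factor must be >= 0, got {s}")
    _check_quanta(mu, upsilon)
    d = math.sqrt(2.0 * s)
    half = 12.0 + d

    def overlap_sq(npts: int) -> float:
        q = np.linspace(-half, half + d, npts)
        integrand = _hermite_function(mu, q - d) * _hermite_function(upsilon, q)
        return float(np.trapezoid(integrand, q)) ** 2

    fine = overlap_sq(n_points)
    coarse = overlap_sq(n_points // 2 + 1)
    err = abs(fine - coarse)
    if err > max(rtol * abs(fine), 1e-12):
        raise RuntimeError(
            f"quadrature not converged: estimated error {err:.2e} "
            f"for FCF({mu},{upsilon}) at S={s}"
        )
    return fine


@dataclass(frozen=True)
class FCProgression:
    """A vibronic progression: FCFs from level mu to upsilon = 0..upsilon_max."""

    s: float
    mu: int
    factors: tuple  # of (upsilon, fcf)

    @property
    def total(self) -> float:
        return sum(f for _, f in self.factors)


def fc_progression(s: float, mu: int = 0, upsilon_max: int = 10) -> FCProgression:
    """Tabulate FCF(mu, upsilon) for upsilon = 0..upsilon_max."""
    if upsilon_max < 0:
        raise ValidationError("upsilon_max must be >= 0")
    factors = tuple(
        (u, fcf_general(s, mu, u) if mu else fcf_poisson(s, u))
        for u in range(upsilon_max + 1)
    )
    return FCProgression(s, mu, factors)
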