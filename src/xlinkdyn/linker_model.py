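"""Bare (pre-networking) dynamics of dumbbell cross-linkers and polymer solutions.

A cross-linker is a pair of endpoints joined by a harmonic spring (constant
``kappa``), each endpoint dragged with coefficient ``gamma_y`` and kicked by
Gaussian noise of strength ``lambda_y``.  In centre-of-mass / extension
coordinates the centre diffuses freely with diffusion coefficient
``D_rho = lambda_y / (4 gamma_y**2)`` while the extension relaxes on the time
scale ``gamma_y / kappa``.  This module evaluates the resulting bare dynamic
structure factors, the Gaussian propagator of a single cross-linker, and the
pre-averaged endpoint density used by the networking potentials.

All quantities are expressed in the dimensionless parameter convention used
throughout the analytic half of the package (gamma = kappa = lambda = 1 for
the reference parameter set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinkerParams",
    "PolymerSolutionParams",
    "DegenerateWavenumberError",
    "InvalidLagError",
    "s0_polymer",
    "s0_linker",
    "linker_propagator",
    "mean_square_extension",
    "endpoint_density_fourier",
]


class DegenerateWavenumberError(ValueError):
    """Raised where a k = 0 mode would require inverting a vanishing spectrum."""


class InvalidLagError(ValueError):
    """Raised for a zero time lag with nonzero extension wavevector (coth pole)."""


@dataclass(frozen=True)
class LinkerParams:
    """Dynamical constants of a dumbbell cross-linker.

    Parameters
    ----------
    gamma_y : drag coefficient per endpoint (force * time / length).
    kappa : spring constant joining the two endpoints (force / length).
    lambda_y : Gaussian noise correlation strength (force**2 * time).
    """

    gamma_y: float = 1.0
    kappa: float = 1.0
    lambda_y: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_y", "kappa", "lambda_y"):
            if not getattr(self, name) > 0:
                raise ValueError(f"LinkerParams.{name} must be strictly positive")

    @property
    def D_rho(self) -> float:
        """Centre-of-mass diffusion coefficient lambda_y / (4 gamma_y**2)."""
        return self.lambda_y / (4.0 * self.gamma_y**2)

    @property
    def extension_coefficient(self) -> float:
        """Pre-averaging coefficient lambda_y / (kappa * gamma_y).

        Multiplies the curvature term of the endpoint density; also the
        steady-state mean-square extension of the spring.
        """
        return self.lambda_y / (self.kappa * self.gamma_y)


@dataclass(frozen=True)
class PolymerSolutionParams:
    """Kinetic coefficient and length parameter of one polymer species."""

    gamma_p: float = 1.0
    L: float = 100.0

    def __post_init__(self) -> None:
        if not (self.gamma_p > 0 and self.L > 0):
            raise ValueError("PolymerSolutionParams fields must be strictly positive")


def s0_polymer(k, omega, p: PolymerSolutionParams):
    """Bare dynamic structure factor of a flexible polymer solution.

    ``S0(k, w) = 2 gamma_p k^2 / (gamma_p^2 w^2 + k^4 / L^2)``; even and
    nonnegative in both arguments, with a diffusive Lorentzian of width
    ``k^2 / (gamma_p L)`` in omega.  The k = 0 mode vanishes identically and
    therefore has no inverse.
    """
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    num = 2.0 * p.gamma_p * k**2
    den = p.gamma_p**2 * omega**2 + k**4 / p.L**2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


def s0_linker(k, omega, D_rho: float):
    """Bare dynamic structure factor of freely diffusing cross-linkers.

    The Brownian-particle spectrum ``D k^2 / (D^2 k^4 + w^2)`` with
    ``D = lambda_y / (4 gamma_y**2)``.
    """
    if not D_rho > 0:
        raise ValueError("D_rho must be strictly positive")
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    num = D_rho * k**2
    den = D_rho**2 * k**4 + omega**2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


def inverse_s0(k, omega, s0_value):
    """Invert a bare spectrum value, rejecting degenerate k = 0 modes."""
    if np.any(np.asarray(k) == 0.0):
        raise DegenerateWavenumberError(
            "S0(0, omega) = 0: the k = 0 mode has no inverse; start grids at the "
            "smallest nonzero wavenumber"
        )
    return 1.0 / s0_value


def linker_propagator(K: float, k: float, dt: float, p: LinkerParams) -> float:
    """Gaussian propagator amplitude of one cross-linker (normalisation N = 1).

    ``exp(-D_rho K^2 dt - (lambda_y / 4 kappa gamma_y) k^2 (1 + coth(kappa dt / gamma_y)))``
    for centre-of-mass wavevector magnitude ``K``, extension wavevector
    magnitude ``k`` and positive time lag ``dt``.  At fixed K = 0 the amplitude
    decays to a finite plateau once ``dt >> gamma_y / kappa``.
    """
    if dt <= 0.0:
        if k != 0.0:
            raise InvalidLagError("dt = 0 with k != 0: coth divergence")
        dt = 0.0
        com = 0.0
    else:
        com = p.D_rho * K**2 * dt
    if k == 0.0:
        ext = 0.0
    else:
        x = p.kappa * dt / p.gamma_y
        # coth(x) -> 1 + 2 exp(-2x) for large x; evaluate stably.
        coth = 1.0 / math.tanh(x) if x < 350.0 else 1.0
        ext = (p.lambda_y / (4.0 * p.kappa * p.gamma_y)) * k**2 * (1.0 + coth)
    return math.exp(-(com + ext))


def mean_square_extension(p: LinkerParams) -> float:
    """Steady-state mean-square extension of the cross-linker spring.

    The second moment of the stationary extension distribution, with
    coefficient ``lambda_y / (kappa gamma_y)`` as used by the pre-averaged
    endpoint density.
    """
    return p.extension_coefficient


def endpoint_density_fourier(k, rho0_k, p: LinkerParams):
    """Fourier mode of the pre-averaged cross-linker endpoint density.

    Each cross-linker carries two endpoints; at finite extension the endpoint
    density picks up a curvature correction, giving the Fourier-space prefactor
    ``2 - (lambda_y / kappa gamma_y) k^2`` acting on the centre-of-mass mode.

    Returns ``(value, breakdown)`` where ``breakdown`` flags wavenumbers at
    which the prefactor is negative (the short-extension expansion no longer
    represents a density there).
    """
    k = np.asarray(k, dtype=float)
    prefactor = 2.0 - p.extension_coefficient * k**2
    value = prefactor * rho0_k
    breakdown = prefactor < 0.0
    if value.ndim == 0:
        return float(value), bool(breakdown)
    return value, breakdown
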