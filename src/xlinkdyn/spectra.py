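"""Coupled correlation spectra of the networked two-species solution.

The networked generating functional is Gaussian in the three density
fluctuation fields, with inverse-spectrum kernels

``B_X(k, w) = 1 / S0_X(k, w) + w_X + v``,   X in {A, B, rho},

where ``v`` is a same-species repulsion added to keep the quadratic form
positive.  The six correlation and cross-correlation spectra are then the
entries of the inverse of the symmetric coupling matrix

``[[B_A, v_AB, v_Arho], [v_AB, B_B, v_Brho], [v_Arho, v_Brho, B_rho]]``.

The collapse threshold ``v_min`` is the largest real root of the cubic
obtained by setting the determinant of this matrix (with the bare inverse
spectra dropped, i.e. diagonal entries ``v + w_X``) to zero: for ``v`` above
that root the quadratic form is positive for every wavenumber and frequency,
since the bare inverse spectra only add positive diagonal weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linker_model import (
    DegenerateWavenumberError,
    LinkerParams,
    PolymerSolutionParams,
    s0_linker,
    s0_polymer,
)
from .networking_potentials import CollapseError, PotentialSet

__all__ = [
    "KernelTriple",
    "CorrelationSpectrum",
    "kernels",
    "correlators",
    "coupling_matrix",
    "v_min",
    "stability_scan",
    "spectrum_grid",
]


@dataclass(frozen=True)
class KernelTriple:
    """Inverse-spectrum kernels at one (k, omega) point."""

    B_A: float
    B_B: float
    B_rho: float


@dataclass
class CorrelationSpectrum:
    """Six correlator arrays on a (k, omega) grid (k strictly nonzero)."""

    k: np.ndarray
    omega: np.ndarray
    AA: np.ndarray
    BB: np.ndarray
    rr: np.ndarray
    Ar: np.ndarray
    Br: np.ndarray
    AB: np.ndarray

    def to_table(self) -> np.ndarray:
        """Flatten to rows (k, omega, S_AA, S_BB, S_rr, S_Ar, S_Br, S_AB)."""
        K, W = np.meshgrid(self.k, self.omega, indexing="ij")
        cols = [K, W, self.AA, self.BB, self.rr, self.Ar, self.Br, self.AB]
        return np.column_stack([c.ravel() for c in cols])


TABLE_HEADER = "k\tomega\tS_AA\tS_BB\tS_rhorho\tS_Arho\tS_Brho\tS_AB"


def kernels(
    k,
    omega,
    pots: PotentialSet,
    v: float,
    polymer_A: PolymerSolutionParams,
    polymer_B: PolymerSolutionParams,
    linker: LinkerParams,
):
    """Inverse-spectrum kernels ``B_X = 1/S0_X + w_X + v`` at (k, omega).

    Accepts scalars or broadcastable arrays; rejects k = 0 where the bare
    spectra vanish and their inverses are undefined.
    """
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(k == 0.0):
        raise DegenerateWavenumberError("k = 0 kernel is undefined (S0 = 0)")
    B_A = np.asarray(1.0 / s0_polymer(k, omega, polymer_A) + pots.w_A + v)
    B_B = np.asarray(1.0 / s0_polymer(k, omega, polymer_B) + pots.w_B + v)
    B_r = np.asarray(1.0 / s0_linker(k, omega, linker.D_rho) + pots.w_rho + v)
    if B_A.ndim == 0:
        return KernelTriple(float(B_A), float(B_B), float(B_r))
    return B_A, B_B, B_r


def coupling_matrix(kt: KernelTriple, pots: PotentialSet) -> np.ndarray:
    """Symmetric 3x3 coupling matrix in the field order (A, B, rho)."""
    return np.array(
        [
            [kt.B_A, pots.v_AB, pots.v_Arho],
            [pots.v_AB, kt.B_B, pots.v_Brho],
            [pots.v_Arho, pots.v_Brho, kt.B_rho],
        ]
    )


def _denominator(B_A, B_B, B_r, pots: PotentialSet):
    """Twice the determinant of the coupling matrix (the printed denominator)."""
    return 2.0 * B_A * (B_B * B_r - pots.v_Brho**2) - 2.0 * (
        B_B * pots.v_Arho**2
        - 2.0 * pots.v_AB * pots.v_Arho * pots.v_Brho
        + B_r * pots.v_AB**2
    )


def correlators(kt: KernelTriple, pots: PotentialSet):
    """The six correlation/cross-correlation values at one (k, omega) point.

    Returns ``(AA, BB, rr, Ar, Br, AB)``; identical to the entries of the
    inverse coupling matrix.  Raises at the collapse threshold where the
    common denominator vanishes.
    """
    den = _denominator(kt.B_A, kt.B_B, kt.B_rho, pots)
    if den == 0.0:
        raise CollapseError("correlator denominator vanished (at-threshold point)")
    AA = (2.0 * kt.B_B * kt.B_rho - 2.0 * pots.v_Brho**2) / den
    BB = (2.0 * kt.B_A * kt.B_rho - 2.0 * pots.v_Arho**2) / den
    rr = (2.0 * kt.B_A * kt.B_B - 2.0 * pots.v_AB**2) / den
    Ar = (-2.0 * kt.B_B * pots.v_Arho + 2.0 * pots.v_AB * pots.v_Brho) / den
    Br = (-2.0 * kt.B_A * pots.v_Brho + 2.0 * pots.v_AB * pots.v_Arho) / den
    AB = (-2.0 * kt.B_rho * pots.v_AB + 2.0 * pots.v_Arho * pots.v_Brho) / den
    return AA, BB, rr, Ar, Br, AB


def v_min(pots: PotentialSet) -> float:
    """Minimum same-species repulsion avoiding collapse.

    The largest real root in ``v`` of the determinant cubic

    ``2 (v+w_A)(v+w_B)(v+w_rho) - 2 v_AB^2 (v+w_rho) - 2 v_Arho^2 (v+w_B)
    - 2 v_Brho^2 (v+w_A) + 4 v_AB v_Arho v_Brho = 0``

    evaluated with the bare inverse spectra dropped.  A cubic always has at
    least one real root; when several are real the largest is the only one
    above which the quadratic form is positive definite.
    """
    wA, wB, wr = pots.w_A, pots.w_B, pots.w_rho
    vab, var, vbr = pots.v_AB, pots.v_Arho, pots.v_Brho
    # expand 2(v+wA)(v+wB)(v+wr) - 2 vab^2 (v+wr) - 2 var^2 (v+wB)
    #        - 2 vbr^2 (v+wA) + 4 vab var vbr  in powers of v
    c3 = 2.0
    c2 = 2.0 * (wA + wB + wr)
    c1 = 2.0 * (wA * wB + wA * wr + wB * wr) - 2.0 * (vab**2 + var**2 + vbr**2)
    c0 = (
        2.0 * wA * wB * wr
        - 2.0 * vab**2 * wr
        - 2.0 * var**2 * wB
        - 2.0 * vbr**2 * wA
        + 4.0 * vab * var * vbr
    )
    roots = np.roots([c3, c2, c1, c0])
    real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real
    return float(np.max(real))


def stability_scan(
    pots: PotentialSet,
    v: float,
    k_grid,
    omega_grid,
    polymer_A: PolymerSolutionParams,
    polymer_B: PolymerSolutionParams,
    linker: LinkerParams,
):
    """Evaluate the correlator denominator over a (k, omega) grid.

    Returns ``(all_stable, min_denominator)`` where ``all_stable`` is true iff
    the denominator is strictly positive everywhere on the grid.
    """
    k_grid = np.atleast_1d(np.asarray(k_grid, dtype=float))
    omega_grid = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    if k_grid.size == 0 or omega_grid.size == 0:
        raise ValueError("stability scan requires nonempty k and omega grids")
    K, W = np.meshgrid(k_grid, omega_grid, indexing="ij")
    B_A, B_B, B_r = kernels(K, W, pots, v, polymer_A, polymer_B, linker)
    den = _denominator(B_A, B_B, B_r, pots)
    min_den = float(den.min())
    return bool(min_den > 0.0), min_den


def spectrum_grid(
    pots: PotentialSet,
    v: float,
    k_grid,
    omega_grid,
    polymer_A: PolymerSolutionParams,
    polymer_B: PolymerSolutionParams,
    linker: LinkerParams,
) -> CorrelationSpectrum:
    """Dense evaluation of all six correlators over the grid.

    The grid must be stable (checked first); with networking switched off the
    diagonal spectra reduce to the bare ``S0`` and the sharp diffusive peaks
    sit at the smallest nonzero (k, omega) grid point.
    """
    k_grid = np.atleast_1d(np.asarray(k_grid, dtype=float))
    omega_grid = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    stable, min_den = stability_scan(
        pots, v, k_grid, omega_grid, polymer_A, polymer_B, linker
    )
    if not stable:
        raise CollapseError(
            f"grid contains unstable points (min denominator {min_den}); "
            "increase the repulsion v"
        )
    K, W = np.meshgrid(k_grid, omega_grid, indexing="ij")
    B_A, B_B, B_r = kernels(K, W, pots, v, polymer_A, polymer_B, linker)
    den = _denominator(B_A, B_B, B_r, pots)
    AA = (2.0 * B_B * B_r - 2.0 * pots.v_Brho**2) / den
    BB = (2.0 * B_A * B_r - 2.0 * pots.v_Arho**2) / den
    rr = (2.0 * B_A * B_B - 2.0 * pots.v_AB**2) / den
    Ar = (-2.0 * B_B * pots.v_Arho + 2.0 * pots.v_AB * pots.v_Brho) / den
    Br = (-2.0 * B_A * pots.v_Brho + 2.0 * pots.v_AB * pots.v_Arho) / den
    AB = (-2.0 * B_r * pots.v_AB + 2.0 * pots.v_Arho * pots.v_Brho) / den
    return CorrelationSpectrum(
        k=k_grid, omega=omega_grid, AA=AA, BB=BB, rr=rr, Ar=Ar, Br=Br, AB=AB
    )
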