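"""Trajectory estimators: persistence length, local nematic order, cross-link
census summaries and dynamic structure factors S(q, omega).

Persistence length uses the bond-angle route lp = -<l_bond> / ln(<cos theta>),
with the cosine averaged over all adjacent bond pairs of a chain and over all
frames, then the per-chain values summarised as mean +/- sd across chains.

S(q, omega) is estimated from collective density modes
rho_q(t) = sum_j exp(-i q . r_j(t)) on the reciprocal lattice of the periodic
box, periodogram over time per mode (optionally Hann-tapered), spherically
averaged over shells of width 2 pi / box, and normalised per particle so that
summing over omega recovers the static structure factor (a discrete Parseval
identity, exact without a taper).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bd_sim import (
    SPECIES_A,
    SPECIES_B,
    SPECIES_LINKER,
    CrossLinkCensus,
    Trajectory,
)

__all__ = [
    "PersistenceResult",
    "SqwEstimate",
    "persistence_length",
    "persistence_length_trajectory",
    "freely_rotating_cos",
    "freely_rotating_lp",
    "local_order_parameter",
    "crosslink_summary",
    "sqw",
    "static_structure_factor",
    "SPECIES_FILTERS",
]

SPECIES_FILTERS = {
    "A": (SPECIES_A,),
    "B": (SPECIES_B,),
    "polymers": (SPECIES_A, SPECIES_B),
    "linkers": (SPECIES_LINKER,),
    "all": (SPECIES_A, SPECIES_B, SPECIES_LINKER),
}


class EmptyNeighborhoodError(ValueError):
    """No bond pairs within the order-parameter cutoff."""


class AntiCorrelatedChainError(ValueError):
    """<cos theta> <= 0: the bond-angle persistence length is undefined."""


@dataclass
class PersistenceResult:
    per_chain: np.ndarray  # lp per chain (inf where <cos theta> == 1)
    mean: float
    sd: float
    mean_bond_length: float
    mean_cos: float

    @property
    def infinite(self) -> bool:
        return bool(np.any(np.isinf(self.per_chain)))


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def persistence_length(
    positions,  # (F, N, 3) or (N, 3)
    chains,  # list of per-chain particle index arrays
    box: float,
) -> PersistenceResult:
    """Bond-angle persistence length per chain, then mean and sd across chains.

    For each chain, ``<l_bond>`` and ``<cos theta>`` are averaged over all
    adjacent bond pairs and all frames; ``lp = -<l_bond>/ln(<cos theta>)``.
    Raises for anticorrelated chains (``<cos theta> <= 0``); a perfectly
    straight chain gives ``inf`` (flagged via :attr:`PersistenceResult.infinite`).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    lps, lbar_all, cos_all = [], [], []
    for idx in chains:
        if len(idx) < 3:
            raise ValueError("persistence length needs chains with >= 2 bonds")
        bonds = _min_image(pos[:, idx[1:], :] - pos[:, idx[:-1], :], box)
        norms = np.linalg.norm(bonds, axis=-1)
        cos = (bonds[:, :-1, :] * bonds[:, 1:, :]).sum(-1) / (
            norms[:, :-1] * norms[:, 1:]
        )
        mean_cos = float(cos.mean())
        mean_len = float(norms.mean())
        lbar_all.append(mean_len)
        cos_all.append(mean_cos)
        if mean_cos <= 0.0:
            raise AntiCorrelatedChainError(
                f"<cos theta> = {mean_cos} <= 0: bond orientations anticorrelated"
            )
        lps.append(math.inf if mean_cos >= 1.0 else -mean_len / math.log(mean_cos))
    per_chain = np.array(lps)
    finite = per_chain[np.isfinite(per_chain)]
    return PersistenceResult(
        per_chain=per_chain,
        mean=float(finite.mean()) if finite.size else math.inf,
        sd=float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
        mean_bond_length=float(np.mean(lbar_all)),
        mean_cos=float(np.mean(cos_all)),
    )


def persistence_length_trajectory(traj: Trajectory, chains, stride: int = 1):
    """Persistence length from every ``stride``-th frame of a trajectory."""
    return persistence_length(traj.positions[::stride], chains, traj.box)


def freely_rotating_cos(k_theta: float, T: float = 1.0) -> float:
    """Boltzmann <cos theta> of the cosine bending potential: coth(k/T) - T/k."""
    k = k_theta / T
    return 1.0 / math.tanh(k) - 1.0 / k


def freely_rotating_lp(k_theta: float, T: float = 1.0, bond_length: float = 1.0):
    """Ideal-chain persistence length -l_bond / ln(coth(k/T) - T/k)."""
    return -bond_length / math.log(freely_rotating_cos(k_theta, T))


def local_order_parameter(
    positions,  # (N, 3) single frame
    chains,
    box: float,
    r_cut: float,
) -> float:
    """Local nematic order from the second Legendre polynomial of bond pairs.

    ``S(r) = (1/2 N_r) sum_{i != j} [3 (b_i . b_j)^2 - 1]`` over ordered pairs
    of backbone unit bond vectors whose anchor monomers (the first monomer of
    each bond) lie within ``r_cut`` (minimum image).  1 = parallel alignment,
    0 = isotropic, -0.5 = perpendicular.
    """
    pos = np.asarray(positions, dtype=float)
    vecs, anchors = [], []
    for idx in chains:
        b = _min_image(pos[idx[1:]] - pos[idx[:-1]], box)
        vecs.append(b / np.linalg.norm(b, axis=-1, keepdims=True))
        anchors.append(pos[idx[:-1]])
    b = np.concatenate(vecs)
    r = np.concatenate(anchors)
    d = _min_image(r[:, None, :] - r[None, :, :], box)
    within = (d**2).sum(-1) <= r_cut**2
    np.fill_diagonal(within, False)
    n_r = int(within.sum())
    if n_r == 0:
        raise EmptyNeighborhoodError(f"no bond pairs within r_cut = {r_cut}")
    dots = b @ b.T
    return float((3.0 * dots**2 - 1.0)[within].sum() / (2.0 * n_r))


def crosslink_summary(census: CrossLinkCensus, burn_in: int = 0) -> dict:
    """Stationary means and fluctuation ranges of each census class.

    Rows with step <= ``burn_in`` are discarded.  The stationarity diagnostic
    per class is |first-half mean - second-half mean| in units of the
    post-burn-in standard deviation (0 for a constant series).
    """
    keep = census.steps >= burn_in
    if not np.any(keep) or keep.sum() < 2:
        raise ValueError("census has no (or too few) rows after the burn-in")
    out = {}
    for name in ("n_AA", "n_BB", "n_AB", "n_single", "n_free", "n_same_chain"):
        x = getattr(census, name)[keep].astype(float)
        sd = float(x.std())
        half = x.size // 2
        drift = abs(x[:half].mean() - x[half:].mean())
        out[name] = {
            "mean": float(x.mean()),
            "sd": sd,
            "min": float(x.min()),
            "max": float(x.max()),
            "stationarity": drift / sd if sd > 0 else 0.0,
        }
    return out


@dataclass
class SqwEstimate:
    q: np.ndarray  # shell centers (multiples of 2 pi / box)
    omega: np.ndarray  # fftshifted angular-frequency grid
    S: np.ndarray  # (n_shells, n_omega)
    counts: np.ndarray  # q-vectors per shell
    window: str  # "rect" or "hann"
    frame_dt: float

    def static_from_parseval(self) -> np.ndarray:
        """sum_omega S(q, omega) domega / (2 pi) per shell."""
        domega = 2.0 * math.pi / (self.omega.size * self.frame_dt)
        return self.S.sum(axis=1) * domega / (2.0 * math.pi)


def _q_lattice(box: float, q_max: float):
    """Reciprocal-lattice vectors with 0 < |q| <= q_max, one per +/-q pair."""
    dq = 2.0 * math.pi / box
    nmax = int(math.floor(q_max / dq))
    pts = []
    for nx in range(0, nmax + 1):
        for ny in range(-nmax, nmax + 1):
            for nz in range(-nmax, nmax + 1):
                if nx == 0 and (ny < 0 or (ny == 0 and nz <= 0)):
                    continue
                q2 = nx * nx + ny * ny + nz * nz
                if q2 > 0 and dq * math.sqrt(q2) <= q_max:
                    pts.append((nx, ny, nz))
    qv = dq * np.array(pts, dtype=float).reshape(len(pts), 3)
    return qv, dq


def _shell_labels(qv, dq, mode):
    """Group q-vectors into shells; returns (labels, shell centers)."""
    qnorm = np.linalg.norm(qv, axis=1)
    if mode == "exact":
        centers, labels = np.unique(np.round(qnorm / dq, 9), return_inverse=True)
        return labels, centers * dq
    if mode != "width":
        raise ValueError("shell_mode must be 'width' or 'exact'")
    idx = np.rint(qnorm / dq).astype(int)
    centers, labels = np.unique(idx, return_inverse=True)
    return labels, centers.astype(float) * dq


def _density_modes(positions, qv):
    """rho_q(t) for frames (F, N, 3) and q-vectors (Nq, 3)."""
    F = positions.shape[0]
    out = np.empty((F, qv.shape[0]), dtype=complex)
    for f in range(F):
        out[f] = np.exp(-1j * (positions[f] @ qv.T)).sum(axis=0)
    return out


def sqw(
    traj: Trajectory,
    species: str = "all",
    q_max: float = 2.0,
    window: str = "rect",
    max_vectors_per_shell: int | None = None,
    subsample_seed: int = 0,
    shell_mode: str = "width",
) -> SqwEstimate:
    """Dynamic structure factor estimate from a uniformly sampled trajectory.

    Periodogram of each density-mode time series, spherically averaged over
    q-shells of width 2 pi / box; no omega averaging.  Normalised per particle
    and scaled so that ``sum_omega S domega / (2 pi)`` equals the static
    structure factor of the same data (exact for the rectangular window).

    ``shell_mode = "exact"`` groups vectors by exact magnitude instead of
    rounding to multiples of 2 pi / box; at the smallest wavenumbers a width
    shell mixes |n|^2 = 1 and 2 lattice vectors, whose relaxation rates differ
    by a factor two, so line-shape fits should use exact shells.
    """
    if traj.n_frames < 2:
        raise ValueError("S(q, omega) needs at least two frames")
    steps = np.diff(traj.steps)
    if steps.size and not np.all(steps == steps[0]):
        raise ValueError("non-uniform frame spacing")
    sel = np.isin(traj.species, SPECIES_FILTERS[species])
    if not np.any(sel):
        raise ValueError(f"no particles of species filter {species!r}")
    qv, dq = _q_lattice(traj.box, q_max)
    if max_vectors_per_shell is not None:
        # the spherical average does not need every lattice vector of a dense
        # outer shell; keep a deterministic random subset per shell
        rng = np.random.default_rng(subsample_seed)
        shell_all, _ = _shell_labels(qv, dq, shell_mode)
        keep = []
        for s in np.unique(shell_all):
            idx = np.where(shell_all == s)[0]
            if idx.size > max_vectors_per_shell:
                idx = rng.choice(idx, size=max_vectors_per_shell, replace=False)
            keep.append(idx)
        qv = qv[np.sort(np.concatenate(keep))]
    rho = _density_modes(traj.positions[:, sel, :], qv)
    F = rho.shape[0]
    n_part = int(sel.sum())
    if window == "hann":
        taper = np.hanning(F)
        taper /= math.sqrt((taper**2).mean())
        rho = rho * taper[:, None]
    elif window != "rect":
        raise ValueError("window must be 'rect' or 'hann'")
    spec = np.abs(np.fft.fft(rho, axis=0)) ** 2 * traj.frame_dt / (F * n_part)
    spec = np.fft.fftshift(spec, axes=0)  # (F, Nq)
    omega = np.fft.fftshift(2.0 * math.pi * np.fft.fftfreq(F, d=traj.frame_dt))

    labels, centers = _shell_labels(qv, dq, shell_mode)
    n_shells = centers.size
    S = np.zeros((n_shells, F))
    counts = np.zeros(n_shells, dtype=int)
    for i, s in enumerate(labels):
        S[s] += spec[:, i]
        counts[s] += 1
    S /= counts[:, None]
    return SqwEstimate(
        q=centers,
        omega=omega,
        S=S,
        counts=counts,
        window=window,
        frame_dt=traj.frame_dt,
    )


def static_structure_factor(
    traj: Trajectory, species: str = "all", q_max: float = 2.0,
    shell_mode: str = "width",
):
    """Shell-averaged static structure factor <|rho_q|^2> / N from the frames."""
    sel = np.isin(traj.species, SPECIES_FILTERS[species])
    qv, dq = _q_lattice(traj.box, q_max)
    rho = _density_modes(traj.positions[:, sel, :], qv)
    sq = (np.abs(rho) ** 2).mean(axis=0) / int(sel.sum())
    labels, centers = _shell_labels(qv, dq, shell_mode)
    out = np.zeros(centers.size)
    counts = np.zeros(centers.size, dtype=int)
    for i, s in enumerate(labels):
        out[s] += sq[i]
        counts[s] += 1
    return centers, out / counts
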