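"""Desk-scale Langevin dynamics of cross-linked semi-flexible bead-spring chains.

Two species of semi-flexible polymers (FENE backbone bonds, WCA excluded
volume, cosine bending) share a periodic box with dumbbell cross-linkers (two
beads joined by a FENE bond).  Reversible cross-linking is an explicit
stochastic rule applied every ``sweep_interval`` steps: an unbound linker bead
binds a nearby eligible monomer with a fixed probability, and every dynamic
bond breaks with a fixed probability, so cross-link numbers rise and then
fluctuate about a stationary mean without any detailed-balance assumption.

All quantities are in reduced Lennard-Jones units (sigma = epsilon = m = 1);
the integrator is velocity Verlet with a Langevin thermostat (friction
``-m v / damp`` plus Gaussian kicks), matching the common molecular-dynamics
convention at damp = 1.0, dt = 0.005.

Species codes: 0 = monomer of species A, 1 = monomer of species B,
2 = linker bead.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from . import _forces

__all__ = [
    "SPECIES_A",
    "SPECIES_B",
    "SPECIES_LINKER",
    "ReactionConfig",
    "SimulationConfig",
    "Topology",
    "SystemState",
    "Trajectory",
    "CrossLinkCensus",
    "OverstretchedBondError",
    "SingularityError",
    "BuildError",
    "IntegrationError",
    "fene_energy",
    "wca_energy",
    "shifted_lj_energy",
    "angle_energy",
    "build_topology",
    "build_system",
    "compute_forces",
    "integrate",
    "reaction_sweep",
    "census_counts",
    "run",
]

SPECIES_A = 0
SPECIES_B = 1
SPECIES_LINKER = 2

# default per-pair-class (epsilon, sigma, r_cut): index = class_i + class_j
# with class 0 = monomer, 1 = linker bead
DEFAULT_PAIR_TABLE = {
    "monomer-monomer": (1.0, 1.0, 1.12),
    "linker-monomer": (1.0, 1.5, 1.68),
    "linker-linker": (1.0, 2.0, 2.24),
}


class OverstretchedBondError(ValueError):
    """A FENE bond extension reached or exceeded R0."""


class SingularityError(ValueError):
    """Pair separation of zero where the potential diverges."""


class BuildError(RuntimeError):
    """Rejection-sampling budget exhausted while packing the box."""


class IntegrationError(RuntimeError):
    """The integrator encountered an invalid state (names the bad bond)."""


@dataclass(frozen=True)
class ReactionConfig:
    """Stochastic binding/unbinding rule applied every ``sweep_interval`` steps.

    ``r_react`` is the capture radius for candidate monomers (formation is
    additionally limited to extensions safely below the FENE R0, since a bond
    beyond R0 has infinite energy); ``p_bond1`` applies to a linker whose
    other bead is free, ``p_bond2`` to one whose other bead is already bound;
    ``p_break`` is the per-sweep unbinding probability of each dynamic bond.
    The defaults are calibrated so that a desk-scale system reaches a
    stationary census with most dumbbells doubly bound while bonds keep
    forming and breaking throughout a production run.
    """

    r_react: float = 1.95
    p_bond1: float = 0.5
    p_bond2: float = 1.0
    p_break: float = 0.0005
    sweep_interval: int = 25
    # Second-bead binding to the first bead's own host chain forms a short
    # local loop that neither bridges chains nor constrains conformations;
    # the published census and network signatures come from chain-bridging
    # links, so same-chain completion is disabled by default.
    allow_same_chain: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    box_length: float = 32.0
    n_chains_A: int = 10
    n_chains_B: int = 10
    chain_length: int = 40
    n_linkers: int = 83
    fene_k: float = 30.0
    fene_R0: float = 1.6
    k_theta: float = 20.0
    pair_table: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_TABLE))
    T: float = 1.0
    damp: float = 1.0
    dt: float = 0.005
    max_displacement: float = 0.1  # per-step cap, triggers only in transients
    reaction: ReactionConfig = field(default_factory=ReactionConfig)
    crosslinking: bool = True
    n_equil_steps: int = 20_000
    n_steps: int = 200_000
    sample_interval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("box_length", "fene_k", "fene_R0", "k_theta", "T", "damp", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"SimulationConfig.{name} must be positive")
        if not self.reaction.r_react < self.box_length / 2:
            raise ValueError("r_react must be below half the box length")

    @property
    def n_monomers(self) -> int:
        return (self.n_chains_A + self.n_chains_B) * self.chain_length

    @property
    def n_particles(self) -> int:
        return self.n_monomers + 2 * self.n_linkers

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def pair_arrays(self):
        """(eps, sigma, rc) arrays indexed by pair class sum."""
        keys = ("monomer-monomer", "linker-monomer", "linker-linker")
        eps = np.array([self.pair_table[k][0] for k in keys])
        sig = np.array([self.pair_table[k][1] for k in keys])
        rc = np.array([self.pair_table[k][2] for k in keys])
        return eps, sig, rc


@dataclass
class Topology:
    """Species labels and permanent connectivity (no coordinates)."""

    species: np.ndarray  # (N,) int8
    bonds: np.ndarray  # (nb, 2) permanent bonds: backbone + dumbbells
    angles: np.ndarray  # (na, 3) backbone triplets
    chains: list  # list of index arrays, one per chain
    chain_of: np.ndarray  # (N,) chain index, -1 for linker beads
    linker_pairs: np.ndarray  # (n_linkers, 2) dumbbell bead indices

    @property
    def n_particles(self) -> int:
        return self.species.shape[0]


@dataclass
class SystemState:
    """Positions, velocities and bond topology under periodic boundaries.

    Positions are continuous (unwrapped); every distance is taken with the
    minimum-image convention, so wrapping is applied only where an algorithm
    requires in-box coordinates.
    """

    positions: np.ndarray  # (N, 3)
    velocities: np.ndarray  # (N, 3)
    topology: Topology
    box: float
    dynamic_partner: np.ndarray  # (N,) partner index or -1 (symmetric)
    forces: np.ndarray | None = None  # cached total forces for the integrator
    _bonds_cache: np.ndarray | None = None
    _excl_cache: np.ndarray | None = None

    @property
    def species(self) -> np.ndarray:
        return self.topology.species

    def invalidate_topology_cache(self) -> None:
        self._bonds_cache = None
        self.forces = None

    def dynamic_bonds(self) -> np.ndarray:
        """(nd, 2) array of (linker bead, monomer) dynamic bonds."""
        linker = np.where(
            (self.species == SPECIES_LINKER) & (self.dynamic_partner >= 0)
        )[0]
        if linker.size == 0:
            return np.empty((0, 2), dtype=np.int64)
        return np.column_stack([linker, self.dynamic_partner[linker]])

    def all_bonds(self) -> np.ndarray:
        if self._bonds_cache is None:
            dyn = self.dynamic_bonds()
            self._bonds_cache = (
                self.topology.bonds if dyn.size == 0
                else np.vstack([self.topology.bonds, dyn])
            )
        return self._bonds_cache

    def exclusions(self) -> np.ndarray:
        """(N, 4) padded exclusion lists for the pair table.

        Only permanently bonded pairs (backbone neighbours, dumbbell partners)
        are excluded; a dynamically bonded linker-monomer pair keeps its
        nonbonded repulsion, which together with the bare FENE of the dynamic
        bond sets the bound separation.
        """
        if self._excl_cache is not None:
            return self._excl_cache
        n = self.positions.shape[0]
        excl = np.full((n, 4), -1, dtype=np.int64)
        fill = np.zeros(n, dtype=np.int64)
        for i, j in self.topology.bonds:
            excl[i, fill[i]] = j
            fill[i] += 1
            excl[j, fill[j]] = i
            fill[j] += 1
        self._excl_cache = excl
        return excl

    def kinetic_temperature(self) -> float:
        n = self.velocities.shape[0]
        return float((self.velocities**2).sum() / (3.0 * n))


@dataclass
class Trajectory:
    """Uniformly sampled frames of a run."""

    steps: np.ndarray  # (F,) step indices
    positions: np.ndarray  # (F, N, 3)
    species: np.ndarray  # (N,)
    box: float
    sample_interval: int
    frame_dt: float  # simulation time between frames
    config_hash: str = ""
    seed: int | None = None
    truncated: bool = False

    @property
    def n_frames(self) -> int:
        return self.steps.shape[0]


@dataclass
class CrossLinkCensus:
    """Per-sweep cross-linker state counts.

    Partition: n_AA + n_BB + n_AB + n_single + n_free = n_linkers at every
    recorded step.  ``n_same_chain`` is the secondary count of doubly-bound
    linkers whose two monomers sit on one chain (a subset of the species-pair
    classes, recorded separately).
    """

    steps: np.ndarray
    n_AA: np.ndarray
    n_BB: np.ndarray
    n_AB: np.ndarray
    n_single: np.ndarray
    n_free: np.ndarray
    n_same_chain: np.ndarray
    n_linkers: int

    def totals(self) -> np.ndarray:
        return self.n_AA + self.n_BB + self.n_AB + self.n_single + self.n_free


# ---------------------------------------------------------------------------
# potential energy functions (per-interaction closed forms)
# ---------------------------------------------------------------------------

def fene_energy(r: float, k: float = 30.0, R0: float = 1.6) -> float:
    """FENE bond energy -(1/2) k R0^2 ln(1 - (r/R0)^2) for 0 <= r < R0."""
    if r < 0:
        raise ValueError("separation must be nonnegative")
    if r >= R0:
        raise OverstretchedBondError(f"FENE extension r = {r} >= R0 = {R0}")
    return -0.5 * k * R0**2 * math.log(1.0 - (r / R0) ** 2)


def wca_energy(r: float, eps: float = 1.0, sigma: float = 1.0) -> float:
    """Purely repulsive (WCA) Lennard-Jones energy, zero beyond 2^(1/6) sigma."""
    if r <= 0:
        raise SingularityError("WCA energy diverges at r = 0")
    if r > 2.0 ** (1.0 / 6.0) * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6) + eps


def shifted_lj_energy(r: float, eps: float, sigma: float, r_c: float) -> float:
    """Truncated-and-shifted Lennard-Jones energy (WCA when r_c = 2^(1/6) sigma)."""
    if r <= 0:
        raise SingularityError("Lennard-Jones energy diverges at r = 0")
    if r >= r_c:
        return 0.0
    sr6 = (sigma / r) ** 6
    src6 = (sigma / r_c) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6) - 4.0 * eps * (src6 * src6 - src6)


def angle_energy(theta: float, k_theta: float = 20.0) -> float:
    """Bending energy k_theta (1 - cos theta); theta = deviation from straight."""
    return k_theta * (1.0 - math.cos(theta))


def bond_energy(r: float, k: float = 30.0, R0: float = 1.6) -> float:
    """Full bond potential: FENE plus the WCA core at sigma = 1."""
    return fene_energy(r, k, R0) + wca_energy(r, 1.0, 1.0)


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def build_topology(config: SimulationConfig) -> Topology:
    """Species labels, permanent bonds and angles (builder arithmetic only)."""
    n_chains = config.n_chains_A + config.n_chains_B
    L = config.chain_length
    n_mono = n_chains * L
    n = n_mono + 2 * config.n_linkers
    species = np.empty(n, dtype=np.int8)
    species[: config.n_chains_A * L] = SPECIES_A
    species[config.n_chains_A * L : n_mono] = SPECIES_B
    species[n_mono:] = SPECIES_LINKER

    chains = [np.arange(c * L, (c + 1) * L) for c in range(n_chains)]
    chain_of = np.full(n, -1, dtype=np.int64)
    for c, idx in enumerate(chains):
        chain_of[idx] = c

    backbone = []
    angles = []
    for idx in chains:
        for a, b in zip(idx[:-1], idx[1:]):
            backbone.append((a, b))
        for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
            angles.append((a, b, c))
    linker_pairs = np.array(
        [(n_mono + 2 * m, n_mono + 2 * m + 1) for m in range(config.n_linkers)],
        dtype=np.int64,
    ).reshape(config.n_linkers, 2)
    bonds = np.array(
        backbone + [tuple(p) for p in linker_pairs], dtype=np.int64
    ).reshape(len(backbone) + config.n_linkers, 2)
    return Topology(
        species=species,
        bonds=bonds,
        angles=np.array(angles, dtype=np.int64).reshape(len(angles), 3),
        chains=chains,
        chain_of=chain_of,
        linker_pairs=linker_pairs,
    )


def _sample_cos_bend(k_theta: float, T: float, rng) -> float:
    """Draw cos(theta) from the bending Boltzmann weight e^{k cos} sin(theta) dtheta."""
    k = k_theta / T
    u = rng.random()
    if k < 1e-12:
        return 2.0 * u - 1.0
    # inverse CDF of p(c) proportional to e^{k c} on [-1, 1]
    return 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * k)) / k


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perp_rotate(prev: np.ndarray, cos_t: float, rng) -> np.ndarray:
    """Unit vector at angle arccos(cos_t) from ``prev``, azimuth uniform."""
    # orthonormal frame around prev
    a = np.array([1.0, 0.0, 0.0]) if abs(prev[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(prev, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(prev, e1)
    phi = 2.0 * math.pi * rng.random()
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t**2))
    return cos_t * prev + sin_t * (math.cos(phi) * e1 + math.sin(phi) * e2)


class _RejectionGrid:
    """Coarse cell hash used only while packing the initial configuration."""

    def __init__(self, box: float, cell: float):
        self.box = box
        self.n = max(1, int(box / cell))
        self.cells: dict[tuple, list] = {}

    def _key(self, p):
        return tuple((np.floor(p / self.box * self.n).astype(int)) % self.n)

    def neighbours(self, p):
        kx, ky, kz = self._key(p)
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    key = ((kx + ox) % self.n, (ky + oy) % self.n, (kz + oz) % self.n)
                    yield from self.cells.get(key, ())

    def add(self, p, payload):
        self.cells.setdefault(self._key(p), []).append((p, payload))


# minimum allowed build separation per pair class (kept a few kT below contact
# so the warm-up run relaxes residual overlaps)
_BUILD_MIN_SEP = {0: 0.9, 1: 1.35, 2: 1.9}


def build_system(config: SimulationConfig, seed: int | None = None) -> SystemState:
    """Pack chains (biased random walks) and dumbbells into the box.

    Chains are grown with bending angles drawn from the cosine-potential
    Boltzmann weight at bond length 0.97 (the FENE+WCA minimum); every
    placement is rejection-tested against already-placed particles.
    Deterministic for a given seed.
    """
    topo = build_topology(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    box = config.box_length
    n = topo.n_particles
    pos = np.empty((n, 3))
    grid = _RejectionGrid(box, cell=2.0)
    budget = 200 * n

    def clear(p, cls):
        for q, qcls in grid.neighbours(p):
            d = p - q
            d -= box * np.round(d / box)
            if (d @ d) < _BUILD_MIN_SEP[cls + qcls] ** 2:
                return False
        return True

    tries = 0
    bond_len = 0.97
    for idx in topo.chains:
        placed = False
        while not placed:
            tries += 1
            if tries > budget:
                raise BuildError("packing budget exhausted while growing chains")
            start = rng.random(3) * box
            if not clear(start, 0):
                continue
            chain_pos = [start]
            direction = _random_unit(rng)

            def self_clear(cand):
                # all but the directly bonded predecessor (at bond length)
                for q in chain_pos[:-1]:
                    d = cand - q
                    d -= box * np.round(d / box)
                    if (d @ d) < _BUILD_MIN_SEP[0] ** 2:
                        return False
                return True

            ok = True
            for _ in range(len(idx) - 1):
                for attempt in range(60):
                    tries += 1
                    cand = (chain_pos[-1] + bond_len * direction) % box
                    if clear(cand, 0) and self_clear(cand):
                        chain_pos.append(cand)
                        direction = _perp_rotate(
                            direction, _sample_cos_bend(config.k_theta, config.T, rng), rng
                        )
                        break
                    direction = _random_unit(rng)
                else:
                    ok = False
                    break
                if tries > budget:
                    raise BuildError("packing budget exhausted while growing chains")
            placed = ok
        for i, p in zip(idx, chain_pos):
            pos[i] = p
            grid.add(p, 0)

    for a, b in topo.linker_pairs:
        for attempt in range(2000):
            tries += 1
            if tries > budget + 2000 * config.n_linkers:
                raise BuildError("packing budget exhausted while placing linkers")
            p1 = rng.random(3) * box
            if not clear(p1, 1):
                continue
            p2 = (p1 + bond_len * _random_unit(rng)) % box
            if clear(p2, 1):
                break
        else:
            raise BuildError("could not place a dumbbell within the attempt budget")
        pos[a], pos[b] = p1, p2
        grid.add(p1, 1)
        grid.add(p2, 1)

    vel = rng.normal(scale=math.sqrt(config.T), size=(n, 3))
    vel -= vel.mean(axis=0)
    return SystemState(
        positions=pos % box,
        velocities=vel,
        topology=topo,
        box=box,
        dynamic_partner=np.full(n, -1, dtype=np.int64),
    )


def build_uniform_system(config: SimulationConfig, seed: int | None = None) -> SystemState:
    """Uniform (structureless) initial positions, Maxwell velocities.

    For free-particle reference runs: the rejection packing of
    :func:`build_system` imprints short-range structure whose relaxation
    contaminates collective density modes at early times, so estimator
    cross-validations against ideal-gas theory start from a true ideal-gas
    configuration instead.  Not suitable for interacting systems (overlaps).
    """
    topo = build_topology(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = topo.n_particles
    vel = rng.normal(scale=math.sqrt(config.T), size=(n, 3))
    vel -= vel.mean(axis=0)
    return SystemState(
        positions=rng.random((n, 3)) * config.box_length,
        velocities=vel,
        topology=topo,
        box=config.box_length,
        dynamic_partner=np.full(n, -1, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# forces and integration
# ---------------------------------------------------------------------------

def compute_forces(state: SystemState, config: SimulationConfig):
    """Conservative forces and potential energy of the current state."""
    n = state.positions.shape[0]
    forces = np.zeros((n, 3))
    eps, sig, rc = config.pair_arrays()
    cls = (state.species == SPECIES_LINKER).astype(np.int64)
    e_pair = _forces.pair_forces(
        state.positions % state.box, cls, state.box, eps, sig, rc,
        state.exclusions(), forces,
    )
    e_bond, bad = _forces.bond_forces(
        state.positions, state.all_bonds(), state.topology.bonds.shape[0],
        state.box, config.fene_k, config.fene_R0, forces,
    )
    if bad >= 0:
        i, j = state.all_bonds()[bad]
        raise IntegrationError(
            f"overstretched FENE bond {bad} between particles {i} and {j}"
        )
    e_angle = _forces.angle_forces(
        state.positions, state.topology.angles, state.box, config.k_theta, forces
    )
    return forces, e_pair + e_bond + e_angle


def integrate(
    state: SystemState,
    config: SimulationConfig,
    n_steps: int,
    rng: np.random.Generator,
    thermostat: bool = True,
) -> SystemState:
    """Advance the state by velocity-Verlet Langevin steps (in place).

    Friction ``-m v / damp`` and Gaussian kicks of per-component variance
    ``2 m T / (damp dt)`` (as force variance) enter the force at every
    evaluation; with the thermostat off the integrator is plain velocity
    Verlet and conserves energy to symplectic accuracy.
    """
    dt = config.dt
    inv_damp = 1.0 / config.damp
    kick_sigma = math.sqrt(2.0 * config.T / (config.damp * dt))
    pos, vel = state.positions, state.velocities

    def total_force():
        f, _ = compute_forces(state, config)
        if thermostat:
            f -= inv_damp * vel
            f += kick_sigma * rng.normal(size=vel.shape)
        return f

    if state.forces is None:
        state.forces = total_force()
    f = state.forces
    cap = config.max_displacement
    cap_v = cap / dt
    for _ in range(n_steps):
        vel += 0.5 * dt * f
        speed = np.sqrt((vel**2).sum(axis=1))
        fast = speed > cap_v
        if np.any(fast):
            # limit the per-step move of runaway particles (reaction transients)
            pos[fast] += dt * vel[fast] * (cap_v / speed[fast])[:, None]
            pos[~fast] += dt * vel[~fast]
        else:
            pos += dt * vel
        f = total_force()
        vel += 0.5 * dt * f
    state.forces = f
    return state


# ---------------------------------------------------------------------------
# reversible cross-linking
# ---------------------------------------------------------------------------

def _formation_radius(config: SimulationConfig) -> float:
    # a FENE bond cannot form at or beyond R0; keep a margin so the freshly
    # formed spring force stays integrable at the working timestep
    return min(config.reaction.r_react, 0.95 * config.fene_R0)


def reaction_sweep(state: SystemState, config: SimulationConfig, rng):
    """One stochastic binding/unbinding sweep; returns the event list.

    Breaking is applied first (each dynamic bond independently with
    ``p_break``), then every still-unbound linker bead draws a uniformly
    chosen eligible monomer within the capture radius and binds with
    ``p_bond1`` (first bead of its dumbbell to bind) or ``p_bond2`` (second).
    Capacity invariants (at most one dynamic bond per linker bead and per
    monomer) hold by construction.
    """
    rc = config.reaction
    events = []
    partner = state.dynamic_partner
    species = state.species
    # --- breaking ---
    dyn = state.dynamic_bonds()
    if dyn.shape[0] and rc.p_break > 0.0:
        for bead, mono in dyn[rng.random(dyn.shape[0]) < rc.p_break]:
            partner[bead] = -1
            partner[mono] = -1
            events.append(("break", int(bead), int(mono)))
    if events:
        state.invalidate_topology_cache()
    # --- binding ---
    if rc.p_bond1 <= 0.0 and rc.p_bond2 <= 0.0:
        return events
    linker_beads = np.where((species == SPECIES_LINKER) & (partner < 0))[0]
    if linker_beads.size == 0:
        return events
    monomers = np.where(species != SPECIES_LINKER)[0]
    r_cap = _formation_radius(config)
    tree = cKDTree(state.positions[monomers] % state.box, boxsize=state.box)
    order = rng.permutation(linker_beads)
    pairs = state.topology.linker_pairs
    # map bead -> its dumbbell partner bead
    other = {int(a): int(b) for a, b in pairs} | {int(b): int(a) for a, b in pairs}
    chain_of = state.topology.chain_of
    for bead in order:
        hits = tree.query_ball_point(state.positions[bead] % state.box, r_cap)
        cands = [monomers[h] for h in hits if partner[monomers[h]] < 0]
        other_host = partner[other[int(bead)]]
        if other_host >= 0 and not rc.allow_same_chain:
            cands = [c for c in cands if chain_of[c] != chain_of[other_host]]
        if not cands:
            continue
        p = rc.p_bond1 if other_host < 0 else rc.p_bond2
        if rng.random() >= p:
            continue
        mono = cands[int(rng.integers(len(cands)))]
        partner[bead] = mono
        partner[mono] = bead
        events.append(("bind", int(bead), int(mono)))
    if events:
        state.invalidate_topology_cache()
    return events


def census_counts(state: SystemState):
    """Classify every dumbbell: (n_AA, n_BB, n_AB, n_single, n_free, n_same_chain)."""
    partner = state.dynamic_partner
    species = state.species
    chain_of = state.topology.chain_of
    n_AA = n_BB = n_AB = n_single = n_free = n_same = 0
    for a, b in state.topology.linker_pairs:
        pa, pb = partner[a], partner[b]
        bound = int(pa >= 0) + int(pb >= 0)
        if bound == 0:
            n_free += 1
        elif bound == 1:
            n_single += 1
        else:
            sa, sb = species[pa], species[pb]
            if sa == SPECIES_A and sb == SPECIES_A:
                n_AA += 1
            elif sa == SPECIES_B and sb == SPECIES_B:
                n_BB += 1
            else:
                n_AB += 1
            if chain_of[pa] == chain_of[pb]:
                n_same += 1
    return n_AA, n_BB, n_AB, n_single, n_free, n_same


# ---------------------------------------------------------------------------
# full workflow
# ---------------------------------------------------------------------------

def run(config: SimulationConfig, state: SystemState | None = None):
    """Equilibrate, then run production with or without cross-linking.

    Returns ``(trajectory, census)``.  Frames are written every
    ``sample_interval`` steps of production (the initial production frame is
    step 0); census rows are recorded every reaction sweep.  Identical config
    and seed give bit-identical results.
    """
    rng = np.random.default_rng(config.seed)
    if state is None:
        state = build_system(config, seed=int(rng.integers(2**31)))
    if config.n_equil_steps > 0:
        # brief reduced-timestep warm-up relaxes residual packing overlaps
        warmup = min(2000, config.n_equil_steps // 2)
        if warmup > 0:
            import dataclasses as _dc

            integrate(state, _dc.replace(config, dt=config.dt / 5.0), warmup, rng)
            state.forces = None
        integrate(state, config, config.n_equil_steps - warmup, rng)

    sweep = config.reaction.sweep_interval
    sample = config.sample_interval
    frames, frame_steps = [], []
    census_rows, census_steps = [], []

    def record_census(step):
        census_steps.append(step)
        census_rows.append(census_counts(state))

    record_census(0)
    if config.n_steps > 0:
        frames.append(state.positions.copy())
        frame_steps.append(0)
        step = 0
        next_sample = sample
        next_sweep = sweep if config.crosslinking else None
        while step < config.n_steps:
            nxt = min(
                t for t in (config.n_steps, next_sample, next_sweep) if t is not None
            )
            integrate(state, config, nxt - step, rng)
            step = nxt
            if step == next_sample:
                frames.append(state.positions.copy())
                frame_steps.append(step)
                next_sample += sample
            if next_sweep is not None and step == next_sweep:
                reaction_sweep(state, config, rng)
                record_census(step)
                next_sweep += sweep

    n_frames = len(frames)
    traj = Trajectory(
        steps=np.array(frame_steps, dtype=np.int64),
        positions=(
            # float32 halves the memory of long trajectories; the estimators
            # (bond angles, density modes) are insensitive at this precision
            np.array(frames, dtype=np.float32)
            if n_frames
            else np.empty((0, state.positions.shape[0], 3), dtype=np.float32)
        ),
        species=state.species.copy(),
        box=state.box,
        sample_interval=sample,
        frame_dt=sample * config.dt,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    rows = np.array(census_rows, dtype=np.int64).reshape(len(census_rows), 6)
    census = CrossLinkCensus(
        steps=np.array(census_steps, dtype=np.int64),
        n_AA=rows[:, 0],
        n_BB=rows[:, 1],
        n_AB=rows[:, 2],
        n_single=rows[:, 3],
        n_free=rows[:, 4],
        n_same_chain=rows[:, 5],
        n_linkers=config.n_linkers,
    )
    return traj, census
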