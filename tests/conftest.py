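"""Shared fixtures: the matched desk-scale run pair and the Brownian reference.

The matched pair (one production run with reversible cross-linking, one
without, identical otherwise) is the package's desk-scale realisation of the
published study conditions: 40-bead semi-flexible chains in equal species
numbers, ~4.2 dumbbell cross-linkers per chain, number density 0.029,
dt = 0.005, T = 1.  It is session-scoped because several acceptance checks
(persistence length, census, local order, dynamic structure factors) read the
same two trajectories.
"""

import dataclasses

import numpy as np
import pytest

from xlinkdyn import bd_sim
from xlinkdyn.cli_io import desk_simulation_config

ACCEPT_SEED = 20260919

# desk-scale study conditions (see docs/methods.md)
N_CHAINS_PER_SPECIES = 12
N_LINKERS = 100
N_EQUIL = 20_000
N_PROD = 400_000
SAMPLE = 20
# persistence/order statistics are taken after the census plateau and initial
# network relaxation
ANALYSIS_START_STEP = 150_000


def chain_indices(traj):
    mono = np.where(traj.species != bd_sim.SPECIES_LINKER)[0]
    return [mono[i : i + 40] for i in range(0, len(mono), 40)]


@pytest.fixture(scope="session")
def matched_runs():
    cfg_free = dataclasses.replace(
        desk_simulation_config(
            seed=ACCEPT_SEED,
            n_chains_per_species=N_CHAINS_PER_SPECIES,
            n_linkers=N_LINKERS,
            crosslinking=False,
            n_equil_steps=N_EQUIL,
            n_steps=N_PROD,
        ),
        sample_interval=SAMPLE,
    )
    traj_free, census_free = bd_sim.run(cfg_free)
    cfg_linked = dataclasses.replace(cfg_free, crosslinking=True)
    traj_linked, census_linked = bd_sim.run(cfg_linked)
    return {
        "config_free": cfg_free,
        "config_linked": cfg_linked,
        "free": (traj_free, census_free),
        "linked": (traj_linked, census_linked),
        "chains": chain_indices(traj_free),
        "analysis_start_frame": ANALYSIS_START_STEP // SAMPLE,
    }


@pytest.fixture(scope="session")
def brownian_traj():
    """Free Brownian particles from a uniform start (no initial structure)."""
    table = {k: (0.0, 1.0, 0.5) for k in
             ("monomer-monomer", "linker-monomer", "linker-linker")}
    cfg = bd_sim.SimulationConfig(
        box_length=32.0, n_chains_A=500, n_chains_B=0, chain_length=1,
        n_linkers=0, pair_table=table, seed=ACCEPT_SEED + 1,
        n_equil_steps=0, n_steps=8192 * 20, sample_interval=20,
    )
    state = bd_sim.build_uniform_system(cfg, seed=ACCEPT_SEED + 2)
    traj, _ = bd_sim.run(cfg, state=state)
    return traj
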