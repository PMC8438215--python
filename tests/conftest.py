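"""Shared fixtures: the default funnel system and a reference campaign.

Expensive session-scoped fixtures are built once: the planted-funnel
system, its topology, and a 20-replica supervised campaign (seeds 0–19)
with kept productive trajectories, reused by the supervision, analysis and
acceptance tests.
"""

import numpy as np
import pytest

import sumdkit as sk
from sumdkit.supervisor import funnel_supervision_config, run_campaign


@pytest.fixture(scope="session")
def funnel_spec():
    return sk.build_funnel_system(seed=0)


@pytest.fixture(scope="session")
def funnel_structure(funnel_spec):
    return funnel_spec.to_structure()


@pytest.fixture(scope="session")
def supervision_cfg():
    return funnel_supervision_config(base_seed=0)


@pytest.fixture(scope="session")
def campaign20(funnel_spec, supervision_cfg):
    """20 supervised replicas (seeds 0–19) with productive trajectories."""
    table, results = run_campaign(
        funnel_spec, supervision_cfg, n_replicas=20, base_seed=0,
        keep_trajectories=True)
    return table, results


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_structure(n_atoms: int, seed: int) -> sk.StructureModel:
    """Small random structure with positive masses; helper for geometry tests."""
    rg = np.random.default_rng(seed)
    return sk.StructureModel(
        atom_name=[f"A{i}" for i in range(n_atoms)],
        element=["C"] * n_atoms,
        residue_name=["RES"] * n_atoms,
        residue_number=np.arange(1, n_atoms + 1),
        insertion_code=[""] * n_atoms,
        chain_id=["A"] * n_atoms,
        mass=rg.uniform(1.0, 20.0, n_atoms),
        coords=rg.normal(0.0, 5.0, (n_atoms, 3)),
    )
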