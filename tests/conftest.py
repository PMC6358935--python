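"""Shared fixtures: the default planted benchmark and its (expensive) CV runs.

The cross-validation fixtures are session-scoped so the full pipeline runs
once and is examined by several tests.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import ksimc


@pytest.fixture(scope="session")
def default_instance() -> ksimc.PlantedInstance:
    return ksimc.generate_planted_instance(seed=0)


@pytest.fixture(scope="session")
def default_sims(default_instance):
    sim_kin = ksimc.build_similarity_matrix(default_instance.kinases)
    sim_sub = ksimc.build_similarity_matrix(default_instance.substrates)
    return sim_kin, sim_sub


@pytest.fixture(scope="session")
def default_cv(default_instance, default_sims):
    """Ten-fold CV of the full pipeline on the default planted instance."""
    sim_kin, sim_sub = default_sims
    return ksimc.cross_validate(
        default_instance.kinases,
        default_instance.substrates,
        default_instance.interaction_list(),
        ksimc.RunConfig(),
        sim_kin=sim_kin,
        sim_sub=sim_sub,
    )


@pytest.fixture(scope="session")
def null_cv(default_instance, default_sims):
    """Same pipeline with the planted structure destroyed: the observed
    pairs are replaced by uniformly random pairs of the same count."""
    sim_kin, sim_sub = default_sims
    il = default_instance.interaction_list()
    null_il = il.with_pairs(ksimc.random_pairs(il.kinase_ids, il.substrate_ids, len(il.pairs), seed=123))
    return ksimc.cross_validate(
        default_instance.kinases,
        default_instance.substrates,
        null_il,
        ksimc.RunConfig(),
        sim_kin=sim_kin,
        sim_sub=sim_sub,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
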