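"""Shared fixtures: the default table and cached simulation groups.

The simulation fixture runs 30 replicas per agent group under the default
task (200 segments, precise or imprecise duration prior) and is shared by
every test that needs full experiments, so the expensive runs happen once
per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from metabandit import AgentSpec, TaskConfig, default_context_tables, run_group

N_REPLICAS = 30
MASTER_SEED = 0


@pytest.fixture(scope="session")
def table():
    return default_context_tables()


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def sim_groups(task_config):
    """30-replica groups of every agent variant used in the analyses."""
    specs = {
        "adp_precise": AgentSpec(type="adp", duration_prior="precise"),
        "efe_precise": AgentSpec(type="efe", duration_prior="precise"),
        "iv_precise": AgentSpec(type="iv", duration_prior="precise"),
        "adp_imprecise": AgentSpec(type="adp", duration_prior="imprecise"),
        "rc": AgentSpec(type="rc"),
    }
    return {name: run_group(spec, N_REPLICAS, task_config,
                            master_seed=MASTER_SEED)
            for name, spec in specs.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
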