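"""Shared fixtures.

The expensive self-assembly demos (three seeds of the small System A
analogue) are run once per session and shared between the dynamics
property tests and the acceptance suite.
"""

from dataclasses import replace

import numpy as np
import pytest

from condgram.forcefield import InteractionParams
from condgram.model_core import ParameterTable
from condgram.simulator import assembly_pipeline
from condgram.synthetic import demo_system


@pytest.fixture(scope="session")
def table():
    return ParameterTable.default()


@pytest.fixture(scope="session")
def params300():
    return InteractionParams.from_conditions(300.0, 0.1)


@pytest.fixture(scope="session")
def assembly_runs():
    """Three independent seeds of the systemA_small assembly pipeline."""
    comp, protocol, _ = demo_system("systemA_small")
    runs = {}
    for seed in (1, 2, 3):
        traj, topo, log = assembly_pipeline(comp, replace(protocol, seed=seed))
        runs[seed] = (traj, topo, log)
    return runs


@pytest.fixture(scope="session")
def noncondensing_run():
    """A Domain-L-dominated analogue that stays dispersed (low H fraction)."""
    from condgram.model_core import SequenceSpec, SystemComposition

    comp, protocol, _ = demo_system("systemA_small")
    low_h = SystemComposition(
        protein_spec=SequenceSpec.from_grammar("R5(N3G2)7"),
        n_protein_chains=comp.n_protein_chains,
        n_rna_chains=comp.n_rna_chains,
        box_edge=comp.box_edge,
        temperature=comp.temperature,
        ionic_strength=comp.ionic_strength,
    )
    protocol = replace(protocol, seed=1, n_steps=30_000)
    traj, topo, log = assembly_pipeline(low_h, protocol)
    return traj, topo, log
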