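"""Shared fixtures: one synthetic benchmark bundle generated per session."""

import pytest

from vcbench.revalidation import AlignmentEvidence
from vcbench.simulate import (SimulationConfig, generate_alignments,
                              generate_callset, generate_toy_genome,
                              generate_truth_set, split_known_truth)


@pytest.fixture(scope="session")
def sim_cfg():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def toy_genome(sim_cfg):
    return generate_toy_genome(sim_cfg)


@pytest.fixture(scope="session")
def truth_set(toy_genome, sim_cfg):
    return generate_truth_set(toy_genome, sim_cfg)


@pytest.fixture(scope="session")
def known_hidden(truth_set, sim_cfg):
    return split_known_truth(truth_set, sim_cfg)


@pytest.fixture(scope="session")
def calls_and_labels(truth_set, sim_cfg, toy_genome):
    return generate_callset(truth_set, sim_cfg, toy_genome)


@pytest.fixture(scope="session")
def alignments_path(toy_genome, truth_set, sim_cfg, tmp_path_factory):
    path = tmp_path_factory.mktemp("aln") / "alignments.sam"
    generate_alignments(toy_genome, truth_set, sim_cfg, str(path))
    return str(path)


@pytest.fixture(scope="session")
def evidence(alignments_path):
    return AlignmentEvidence(alignments_path)
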