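"""Shared fixtures: synthetic genomes and a trained filter model.

Everything is generated programmatically and seeded, so the suite needs no
data files and is fully deterministic.
"""

import pytest

from genescout.pipeline import run_search, train_filter_from_candidates
from genescout.regions import NNConfig, PipelineConfig
from genescout.synthetic import SimConfig, generate_fixture


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig(nn=NNConfig(seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """Five planted genes at 10% ortholog divergence plus two absent queries."""
    return generate_fixture(
        SimConfig(
            seed=7,
            n_genes=5,
            contig_length=200_000,
            divergence=0.1,
            n_absent_queries=2,
        )
    )


@pytest.fixture(scope="session")
def training_fixture():
    """A larger fixture with decoy paralogs and pseudogenes, used to train
    the result filter independently of the evaluation fixtures."""
    return generate_fixture(
        SimConfig(
            seed=1,
            n_genes=15,
            n_paralogs=8,
            n_pseudogenes=5,
            n_absent_queries=8,
            contig_length=700_000,
            divergence=0.1,
        )
    )


@pytest.fixture(scope="session")
def training_run(training_fixture, pipeline_config):
    """Unfiltered pipeline run on the training fixture (raw candidates)."""
    return run_search(
        training_fixture.genome,
        training_fixture.queries,
        config=pipeline_config,
        no_filter=True,
    )


@pytest.fixture(scope="session")
def trained_model(training_run, training_fixture, pipeline_config):
    """Filter trained and calibrated on the training fixture's candidates."""
    return train_filter_from_candidates(
        training_run.candidates, training_fixture.truth, pipeline_config
    )
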