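"""Shared fixtures: one small simulated cross reused across test modules."""

import pytest

from hybridseer import simulate as sim
from hybridseer.config import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        genome_length=150_000,
        n_genes=75,
        gene_length_mean=1_000,
        coverage=20.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_cross(small_config):
    """Parents, gene annotation, F1 child and truth at desk scale."""
    maternal, paternal, ancestral = sim.simulate_parents(small_config)
    genes = sim.emit_gene_annotation(small_config)
    child, truth = sim.simulate_offspring(
        maternal, paternal, small_config, genes=genes
    )
    return {
        "config": small_config,
        "maternal": maternal,
        "paternal": paternal,
        "ancestral": ancestral,
        "genes": genes,
        "child": child,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_reads(small_cross):
    return sim.simulate_reads(small_cross["child"], small_cross["config"])
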