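import numpy as np
import pytest

from islanddiff import SimulationConfig, emit_calls, simulate_genome, simulate_tags


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_chrom=2,
        chrom_length=250_000,
        n_islands=12,
        n_genes=16,
        n_peaks=6,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """One fully simulated experiment shared across read-only tests."""
    genome, truth = simulate_genome(small_config)
    libraries = {
        s: simulate_tags(genome, small_config, s) for s in ("WT", "mut", "input")
    }
    islands, peaks = emit_calls(genome, libraries)
    return genome, truth, libraries, islands, peaks


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
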