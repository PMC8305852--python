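import numpy as np
import pytest

from dhblocks import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    """Compact population: 1 chromosome x 2 Mb, ~200 markers, 20 lines."""
    return sim.SimulationConfig(
        chrom_lengths={"A03": 2_000_000},
        marker_density=1e-4,
        n_dh_lines=20,
        crossover_rate_lambda=1.0,
        causal_region=sim.CausalRegion("A03", 600_000, 1_200_000, "P1"),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return sim.simulate_population(small_config)


@pytest.fixture(scope="session")
def noiseless_population():
    cfg = sim.SimulationConfig(
        chrom_lengths={"A03": 2_000_000},
        marker_density=1e-4,
        n_dh_lines=10,
        crossover_rate_lambda=1.0,
        genotype_error_eps=0.0,
        missing_rate=0.0,
        causal_region=sim.CausalRegion("A03", 600_000, 1_200_000, "P1"),
        seed=23,
    )
    return sim.simulate_population(cfg)


def marker_positions(markers, chrom):
    return [m.position for m in markers if m.chromosome == chrom]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
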