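import numpy as np
import pytest

from ureotype import SimConfig, simulate_study
from ureotype.synthetic_data import simulate_marker_pairs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_config():
    """A compact multi-site study used across module tests.

    Wide divergence spacing keeps every genome's amplicon below the
    clustering threshold against every other, so true OTU count equals
    genome count.
    """
    return SimConfig(
        seed=11,
        n_lineages=2,
        genomes_per_lineage=10,
        n_sites=4,
        core_otus=3,
        site_specific_otus=2,
        reads_per_site=60,
        per_base_error=0.0,
        divergence_grid=tuple(np.linspace(0.015, 0.045, 10).round(6)),
        rate_ratio_rho=8.0,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_genomes(small_config):
    return simulate_marker_pairs(small_config)


def mutate_seq(seq: str, positions, rng=None) -> str:
    """Substitute the given positions to a different base (deterministic)."""
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)
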