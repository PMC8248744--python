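import numpy as np
import pytest

from hapbsa.config import CausalLocus, CnvLocus, SimConfig
from hapbsa.simulate import simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced experiment: 2 Mb genome, one strongly selected locus."""
    return SimConfig(
        chromosome_lengths=(1_000_000, 600_000, 400_000),
        snp_density=0.001,
        causal_loci=(CausalLocus("chr1", 300_000, 0.9, 0.1),),
        cnv_locus=None,
        dna_depth_mean=60.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    return simulate_experiment(small_config, emit_rna=False)


@pytest.fixture(scope="session")
def dosage_config() -> SimConfig:
    """Small genome carrying a 5-gene triplicated block, deep sequencing,
    no cis-eQTL (pure dosage)."""
    return SimConfig(
        chromosome_lengths=(400_000, 300_000, 200_000),
        snp_density=0.002,
        causal_loci=(),
        # genes tile every 2800 bp; this span covers exactly 5 of them
        cnv_locus=CnvLocus("chr2", 100_801, 114_000, 3),
        cis_eqtl=(),
        dna_depth_mean=200.0,
        rna_depth_mean=400.0,
        pool_size=200,
        n_females=200,
        seed=3,
    )


def fixed_population(config: SimConfig, resistant: bool, founders=None):
    """A population fixed for the resistant (or susceptible) haplotype."""
    from hapbsa.simulate import PopulationState, make_founders

    if founders is None:
        founders = make_founders(config)
    s = founders.n_informative
    h = np.ones((config.n_females, 2, s), np.uint8) if resistant else np.zeros(
        (config.n_females, 2, s), np.uint8
    )
    males = h[: config.n_males, 0, :].copy()
    return PopulationState(h, males, 0, "selected" if resistant else "control", founders)
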