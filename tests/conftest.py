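import numpy as np
import pytest

from sweepscan.core import HaplotypeSet
from sweepscan.simulate import SimulationConfig, SweepConfig, simulate_two_pop


def make_hapset(alleles, positions=None, pops=None, chrom="1"):
    """Build a HaplotypeSet from a plain allele matrix (rows=haplotypes)."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_site = alleles.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = np.arange(1, n_site + 1) * 1000
    if pops is None:
        pops = ["A"] * (n_hap // 2) + ["B"] * (n_hap - n_hap // 2)
    return HaplotypeSet(
        alleles=alleles,
        positions=np.asarray(positions),
        chromosome=np.array([chrom] * n_site, dtype=object),
        sample_ids=[f"s{i}" for i in range(n_hap // 2)],
        pop_of_haplotype=np.array(pops, dtype=object),
    )


@pytest.fixture
def hapset_factory():
    return make_hapset


@pytest.fixture(scope="session")
def sweep_sim():
    """One modest sweep simulation shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        sweep=SweepConfig(enabled=True),
        sweep_gene_set="force_in",
    )
    return simulate_two_pop(cfg)


@pytest.fixture(scope="session")
def neutral_sim():
    cfg = SimulationConfig(seed=7)
    return simulate_two_pop(cfg)
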