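import logging

import pytest

from jumboclade import sim

logging.getLogger("jumboclade").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_clade() -> sim.SimulatedClade:
    """Four-genome clade, small enough for per-module tests."""
    cfg = sim.CladeSimConfig(
        n_genomes=4, core_n=25, accessory_pool=16, accessory_rate=0.25,
        p_sub=0.05, gene_len_range=(120, 260), dtr_fraction=0.5,
        host_implants=(sim.HostImplant("Bacteroidota", 6, 0.05),
                       sim.HostImplant("Pseudomonadota", 2, 0.05)),
        n_decoy_refs=12, seed=42)
    return sim.simulate_clade(cfg)


@pytest.fixture(scope="session")
def sibling_pair() -> sim.SimulatedClade:
    """Two sibling genomes at p_sub = 0.05 with no accessory content."""
    cfg = sim.CladeSimConfig(
        n_genomes=2, core_n=40, accessory_pool=0, p_sub=0.05,
        gene_len_range=(150, 250), host_implants=(), dtr_fraction=0.0,
        seed=7)
    return sim.simulate_clade(cfg)
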