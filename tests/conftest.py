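import numpy as np
import pytest

import microdepth as m


@pytest.fixture(scope="session")
def ancestor10k():
    return m.generate_ancestor(10_000, 0.5, seed=101)


@pytest.fixture(scope="session")
def clonal_set(ancestor10k):
    return m.derive_strain_set(ancestor10k, 1, (0.0, 0.0), seed=1)


@pytest.fixture(scope="session")
def single_abundance():
    return m.AbundanceProfile(np.array([1.0]))


@pytest.fixture(scope="session")
def mix_set(ancestor10k):
    """A 5-strain community on the 10 kb ancestor."""
    sset = m.derive_strain_set(ancestor10k, 5, (0.005, 0.02), seed=21)
    ab = m.sample_lognormal_abundances(5, 1.0, seed=22)
    return sset, ab


@pytest.fixture(scope="session")
def q20_recruits(tmp_path_factory, mix_set, ancestor10k):
    """A small Q20 mixed metagenome round-tripped through FASTQ/SAM."""
    sset, ab = mix_set
    prefix = tmp_path_factory.mktemp("q20mix") / "sim"
    sim = m.simulate_metagenome(sset, ab, 600, 150, m.Q20, seed=23,
                                out_prefix=prefix)
    reads = m.load_alignments(sim.sam, ancestor10k)
    return sim, reads
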