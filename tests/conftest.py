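import numpy as np
import pytest

from ctlineage.clock_haplotypes import ClockLocus, HaplotypeTable


@pytest.fixture
def locus9():
    """A 9-CpG clock island (IRX2-like)."""
    return ClockLocus("IRX2", "chr5", tuple(2751000 + 20 * i
                                            for i in range(9)))


@pytest.fixture
def locus16():
    """A 16-CpG clock island (ZNF454-like)."""
    return ClockLocus("ZNF454", "chr5", tuple(178368000 + 10 * i
                                              for i in range(16)))


@pytest.fixture
def make_table(locus16):
    """Factory for haplotype tables over the 16-CpG locus (or shorter)."""

    def factory(counts, sample_id="s1", locus=None):
        locus = locus or locus16
        L = len(next(iter(counts)))
        return HaplotypeTable(sample_id=sample_id, locus=locus,
                              counts=dict(counts),
                              site_positions=locus.cpg_positions[:L])

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
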