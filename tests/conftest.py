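from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nanocirc import GeneModel, GenomicInterval

settings.register_profile(
    "suite", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_model(rng):
    """A 3-exon gene on a 1200 nt locus starting at genomic 5000."""
    seq = random_dna(rng, 1200)
    exons = [GenomicInterval("chrT", 5100, 5200),
             GenomicInterval("chrT", 5400, 5550),
             GenomicInterval("chrT", 5800, 5950)]
    return GeneModel(gene_id="toy", locus=GenomicInterval("chrT", 5000, 6200),
                     exons=exons, sequence=seq)


@pytest.fixture
def seven_exon_model(rng):
    """A 7-exon gene, the shape of the targeted locus."""
    from nanocirc import SimConfig, make_gene
    return make_gene(SimConfig(seed=11), np.random.default_rng(11))
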