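import numpy as np
import pytest

from rnaloci.encoding import ConservationTrack
from rnaloci.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """Two tiny in-memory chromosomes (dict genomes are valid handles)."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    return {
        "chrA": "".join(rng.choice(bases, size=600)),
        "chrB": "".join(rng.choice(bases, size=400)),
    }


@pytest.fixture
def toy_track(toy_genome):
    track = ConservationTrack()
    rng = np.random.default_rng(8)
    for chrom, seq in toy_genome.items():
        track.set_dense(chrom, rng.normal(0.0, 1.0, size=len(seq)))
    return track


def iv(chrom="chrA", start=0, end=100, strand="+", name=".", score=None):
    return GenomicInterval(chrom, start, end, strand, name, score)
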