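import numpy as np
import pytest

from mutpat import Genome, Variant


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    # hand-built contigs with known motifs:
    #   chr1: ACAC... alternating (A[C>A]A contexts at odd positions)
    #   chr2: random-looking fixed sequence
    chr1 = "ACACACACACACACACACAC"
    chr2 = "TTGCAGGTACCATGGTTACGGATCCTAGGCAT"
    return Genome({"chr1": chr1, "chr2": chr2})


@pytest.fixture
def random_genome(rng):
    seqs = {
        f"chr{i+1}": "".join(rng.choice(list("ACGT"), size=3000)) for i in range(2)
    }
    return Genome(seqs)


def make_snv(genome: Genome, contig: str, pos: int, alt: str, sample="s1") -> Variant:
    ref = genome.fetch(contig, pos, pos + 1)
    assert ref != alt
    return Variant(contig, pos, ref, alt, sample)
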