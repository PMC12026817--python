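import numpy as np
import pytest

from spliceclass import GeneSpec, make_toy_locus
from spliceclass.genome import GeneModel, GenomeSequence, TranscriptModel


@pytest.fixture(scope="session")
def poison_locus():
    """Three-exon gene with a poison exon in intron 1 and a 3'UTR intron."""
    return make_toy_locus(GeneSpec(poison=(1, 18, 20, 20), utr3_intron=(10, 30), seed=3))


@pytest.fixture(scope="session")
def frameshift_locus():
    """Four-exon gene where skipping exon 1 (100 nt) shifts the frame."""
    return make_toy_locus(
        GeneSpec(
            exon_coding=(60, 100, 101, 60),
            intron_lengths=(80, 80, 80),
            skip_exon=1,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def nmd_gene():
    """Hand-built plus-strand gene for NMD-rule arithmetic.

    Exons [0,100), [200,300), [400,500); CDS is poly-C ('CCC' codons, never
    a stop) from the ATG at 0 to the TAA at 488. Intron 1 carries a TAA at
    120 (in frame for a junction retaining [100,150)); intron 2 carries a
    TAA at 310 (in frame for a junction retaining [300,380)).
    """
    e1 = "ATG" + "C" * 97
    i1 = "C" * 20 + "TAA" + "C" * 77
    e2 = "C" * 100
    i2 = "C" * 10 + "TAA" + "C" * 87
    e3 = "C" * 88 + "TAA" + "C" * 9
    seq = e1 + i1 + e2 + i2 + e3
    genome = GenomeSequence({"chrN": seq})
    tx = TranscriptModel(
        "TXN", "protein_coding", [(0, 100), (200, 300), (400, 500)],
        start_codon=0, stop_codon=488,
    )
    gene = GeneModel(
        "GN", "chrN", "+", 0, 500,
        start_codons={0}, stop_codons={488}, transcripts=[tx],
    )
    return gene, genome


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
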