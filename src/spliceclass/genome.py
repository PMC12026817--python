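"""Genome sequence and gene-model containers.

Internal coordinates are 0-based half-open everywhere; GTF (1-based
inclusive) is converted at the boundary. Junction identity is the intron
interval (chrom, intron_start, intron_end, strand) where intron_start is
the first intronic base. Codon positions (start/stop) are stored as the
genomic coordinate of the codon's first base *in transcription order*:
on '-' strand that is the larger genomic coordinate of the codon.

Classification needs only start and stop codons from the annotation —
the minimal-annotation premise of the classifier — so CDS features are
deliberately ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pyfaidx
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_VALID_NT = set("ACGTN")

#: transcript_type values treated as productive for the annotation bits.
PRODUCTIVE_TRANSCRIPT_TYPES = frozenset({"protein_coding"})


class GenomeSequence:
    """Uppercase in-memory genome with strand-aware subsequence fetch."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_NT
            if bad:
                raise ValueError(
                    f"record {name!r} contains non-nucleotide characters: {sorted(bad)}"
                )
            self.sequences[name] = seq
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence [start, end); reverse complement on '-' strand."""
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if start < 0 or end > self.lengths[chrom] or start > end:
            raise ValueError(
                f"fetch [{start}, {end}) out of bounds for {chrom} "
                f"(length {self.lengths[chrom]})"
            )
        seq = self.sequences[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def load_genome(fasta_path) -> GenomeSequence:
    """Load a FASTA genome (an index is created if absent; lowercase normalized)."""
    try:
        fa = pyfaidx.Fasta(str(fasta_path))
    except ValueError as e:
        raise ValueError(f"invalid FASTA {fasta_path}: {e}") from e
    return GenomeSequence({name: str(fa[name][:]) for name in fa.keys()})


def fetch_spliced_sequence(
    genome: GenomeSequence, exon_chain, strand: str, chrom: str
) -> str:
    """Concatenate exon sequences in transcription order (revcomp chain on '-')."""
    prev_end = None
    for s, e in exon_chain:
        if s >= e:
            raise ValueError(f"empty or inverted exon ({s}, {e})")
        if prev_end is not None and s < prev_end:
            raise ValueError(f"exon ({s}, {e}) overlaps or precedes previous exon")
        prev_end = e
    plus = "".join(genome.fetch(chrom, s, e, "+") for s, e in exon_chain)
    return reverse_complement(plus) if strand == "-" else plus


@dataclass
class TranscriptModel:
    transcript_id: str
    transcript_type: str
    exons: list[tuple[int, int]]  # sorted by genomic position, non-overlapping
    start_codon: int | None = None  # first base in transcription order
    stop_codon: int | None = None

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Intron intervals between consecutive exons (len = n_exons - 1)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    @property
    def is_productive_type(self) -> bool:
        return self.transcript_type in PRODUCTIVE_TRANSCRIPT_TYPES

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    """A gene with the anchors the classifier needs: start/stop codons and junctions."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    start_codons: set[int] = field(default_factory=set)  # transcription-order first base
    stop_codons: set[int] = field(default_factory=set)
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def classifiable(self) -> bool:
        """Classification needs at least one annotated start AND stop codon."""
        return bool(self.start_codons) and bool(self.stop_codons)

    @property
    def annotated_junctions(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for t in self.transcripts:
            out.update(t.junctions)
        return out

    @property
    def annotated_productive_junctions(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for t in self.transcripts:
            if t.is_productive_type:
                out.update(t.junctions)
        return out

    # -- transcription-order helpers ------------------------------------
    def to_oriented_point(self, pos: int) -> int:
        """Map a genomic base to an offset that increases with transcription."""
        return pos - self.start if self.strand != "-" else (self.end - 1) - pos

    def to_oriented_interval(self, start: int, end: int) -> tuple[int, int]:
        if self.strand != "-":
            return start - self.start, end - self.start
        return self.end - end, self.end - start

    def cds_core(self) -> tuple[int, int]:
        """Transcription-order interval from the most downstream START to the
        most upstream STOP (stop codon included); junctions entirely outside
        it are UTR-ambiguous."""
        if not self.classifiable:
            raise ValueError(f"gene {self.gene_id} has no start/stop codons")
        md_start = max(self.to_oriented_point(p) for p in self.start_codons)
        mu_stop = min(self.to_oriented_point(p) for p in self.stop_codons)
        return md_start, mu_stop + 3


def _codon_first_base(records, strand: str) -> int | None:
    """First base in transcription order of a (possibly exon-split) codon feature."""
    if not records:
        return None
    if strand == "-":
        return max(r.end for r in records) - 1  # GTF end is 1-based inclusive
    return min(r.start for r in records) - 1


def load_gene_models(gtf_path) -> list[GeneModel]:
    """Parse a Gencode-dialect GTF into GeneModel objects.

    Requires gene/transcript/exon records; start_codon and stop_codon
    features anchor classification. Genes lacking either codon are kept
    but marked non-classifiable. Transcripts with overlapping exons are
    rejected with a warning; the gene is kept.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("gene_id", g.attributes.get("gene_name", [g.id]))[0]
        gene = GeneModel(
            gene_id=gene_id,
            chrom=g.seqid,
            strand=g.strand,
            start=g.start - 1,
            end=g.end,
        )
        for t in db.children(g, featuretype="transcript"):
            tid = t.attributes.get(
                "transcript_id", t.attributes.get("transcript_name", [t.id])
            )[0]
            ttype = t.attributes.get(
                "transcript_type", t.attributes.get("transcript_biotype", ["unknown"])
            )[0]
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(t, featuretype="exon")
            )
            if not exons:
                log.warning("transcript %s has no exons; skipped", tid)
                continue
            if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
                log.warning("transcript %s has overlapping exons; rejected", tid)
                continue
            start_c = _codon_first_base(
                list(db.children(t, featuretype="start_codon")), g.strand
            )
            stop_c = _codon_first_base(
                list(db.children(t, featuretype="stop_codon")), g.strand
            )
            tm = TranscriptModel(tid, ttype, exons, start_c, stop_c)
            gene.transcripts.append(tm)
            if start_c is not None:
                gene.start_codons.add(start_c)
            if stop_c is not None:
                gene.stop_codons.add(stop_c)
        for p in list(gene.start_codons) + list(gene.stop_codons):
            if not (gene.start <= p < gene.end):
                raise ValueError(
                    f"codon position {p} outside span of gene {gene.gene_id}"
                )
        genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def gene_models_to_gtf(genes: list[GeneModel]) -> str:
    """Serialize gene models to GTF text (round-trips junctions and codons)."""

    def attrs(gene, t=None):
        a = (
            f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_id}"; '
            f'gene_type "protein_coding";'
        )
        if t is not None:
            a += (
                f' transcript_id "{t.transcript_id}"; '
                f'transcript_name "{t.transcript_id}"; '
                f'transcript_type "{t.transcript_type}";'
            )
        return a

    lines: list[str] = []

    def row(feat, s, e, gene, t=None):
        lines.append(
            f"{gene.chrom}\tspliceclass\t{feat}\t{s + 1}\t{e}\t.\t"
            f"{gene.strand}\t.\t{attrs(gene, t)}"
        )

    for gene in genes:
        row("gene", gene.start, gene.end, gene)
        for t in gene.transcripts:
            ts, te = t.span
            row("transcript", ts, te, gene, t)
            for es, ee in t.exons:
                row("exon", es, ee, gene, t)
            for feat, pos in (("start_codon", t.start_codon), ("stop_codon", t.stop_codon)):
                if pos is None:
                    continue
                s, e = (pos - 2, pos + 1) if gene.strand == "-" else (pos, pos + 3)
                row(feat, s, e, gene, t)
    return "\n".join(lines) + "\n"


def write_gene_models_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write(gene_models_to_gtf(genes))


class GeneIndex:
    """Interval index of genes for junction -> overlapping-gene queries."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def overlapping(self, chrom: str, start: int, end: int, strand: str = ".") -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand in ("+", "-"):
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))
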