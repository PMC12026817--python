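"""Productive / unproductive classification of splice junctions.

The classifier asks, for every junction, whether it can participate in
an open reading frame running from an annotated start codon to an
annotated stop codon without hitting a premature termination codon
(PTC). It explores exon paths — alternating exonic segments and
junctions — breadth-first, memoizing on the pair (last junction,
reading-frame phase): if one PTC-free path reaches a given 5' splice
site in a given frame, every continuation behaves identically, so each
such state is expanded at most once and the whole search needs at most
3 x (n_junctions + 1) expansions.

Phase is the number of bases of the current codon already consumed at a
junction's 3' splice site. Because the partially consumed codon bases
are always the last ``phase`` exonic bases before that junction's donor,
the (junction, phase) pair fully determines the translation state.

Results are reported as four bitwise flags per junction (decimal weight
in parentheses):

  bit0 (1)  UTR        — junction lies entirely outside the span from the
                         most downstream annotated START to the most
                         upstream annotated STOP;
  bit1 (2)  productive — the search found a PTC-free START->STOP path
                         through the junction, combining observed and
                         annotated-productive junctions;
  bit2 (4)  annotated  — junction occurs in any annotated transcript;
  bit3 (8)  productive-annotated — junction occurs in a protein_coding
                         transcript (implies bit2).

Example: a junction in a UTR region that the search deems unproductive
but that is annotated in a productive transcript has flags 1101, decimal
13.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import pandas as pd

from .clustering import IntronCluster
from .genome import GeneIndex, GeneModel, GenomeSequence
from .junctions import Junction

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_MAX_EXON_LENGTH = 5000
DEFAULT_MAX_JUNCTIONS_PER_GENE = 1000

#: decimal flag sets used when tallying categories downstream
UNPRODUCTIVE_FLAGS = frozenset({0, 1, 4, 5})
UTR_AMBIGUOUS_FLAGS = frozenset({1, 4})


def first_inframe_stop(seq: str, phase: int) -> int | None:
    """Offset of the first stop codon in ``seq`` read in the given phase.

    ``phase`` bases of the current codon were already consumed upstream,
    so the first complete codon starts at offset (3 - phase) mod 3.
    Codons containing N never count as stops.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    for i in range((3 - phase) % 3, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


def is_utr_junction(junction: Junction, gene: GeneModel) -> bool:
    """True iff the intron lies entirely outside the gene's START..STOP core."""
    lo, hi = gene.cds_core()
    js, je = gene.to_oriented_interval(junction.start, junction.end)
    return je <= lo or js >= hi


@dataclass(frozen=True)
class ClassificationRecord:
    junction: Junction
    utr: bool
    orf_productive: bool
    is_annotated: bool
    is_productive_annotated: bool

    @property
    def flag(self) -> int:
        return (
            int(self.utr)
            + 2 * int(self.orf_productive)
            + 4 * int(self.is_annotated)
            + 8 * int(self.is_productive_annotated)
        )

    @property
    def category(self) -> str:
        return categorize(self.flag)


def assemble_flags(
    junction: Junction | None,
    utr: bool,
    orf_productive: bool,
    is_annotated: bool,
    is_productive_annotated: bool,
) -> ClassificationRecord:
    """Build a ClassificationRecord, enforcing bit3 => bit2."""
    if is_productive_annotated and not is_annotated:
        raise ValueError(
            "a junction in a productive annotated transcript is necessarily annotated "
            "(bit3 requires bit2)"
        )
    return ClassificationRecord(
        junction, bool(utr), bool(orf_productive), bool(is_annotated),
        bool(is_productive_annotated),
    )


def categorize(flag: int, in_gene: bool = True) -> str:
    """Map a decimal flag to productive / unproductive / UTR.

    Junctions outside any classifiable gene, junctions with the UTR bit
    set, and flag 4 (annotated only, no productive evidence either way)
    are UTR-ambiguous. Of the rest, any productive evidence (bit1 or
    bit3) makes the junction productive; flag 0 is unproductive.
    """
    if not 0 <= flag <= 15:
        raise ValueError(f"flag {flag} out of range")
    if not in_gene:
        return "UTR"
    if flag & 1 or flag == 4:
        return "UTR"
    if flag & 2 or flag & 8:
        return "productive"
    return "unproductive"


class GeneSkipped(Exception):
    """Raised when a gene cannot be classified (missing codons or too many junctions)."""


class _GeneSearch:
    """One gene's BFS, in transcription-oriented coordinates.

    Oriented offset o of genomic base g: o = g - start on '+',
    o = (end - 1) - g on '-'; intron [a, b) maps to an oriented interval
    whose low end is the donor and high end the acceptor.
    """

    START = -1  # sentinel junction index for start-codon states

    def __init__(self, gene: GeneModel, genome: GenomeSequence, max_exon_length: int):
        self.gene = gene
        self.max_exon_length = max_exon_length
        self.seq = genome.fetch(gene.chrom, gene.start, gene.end, gene.strand)
        self.starts = sorted(gene.to_oriented_point(p) for p in gene.start_codons)
        self.stops = frozenset(gene.to_oriented_point(p) for p in gene.stop_codons)
        self.scan_limit = max(self.stops) + 3
        self.expansions = 0

    def orient_junction(self, j: Junction) -> tuple[int, int]:
        a, b = self.gene.to_oriented_interval(j.start, j.end)
        return a, b

    def _partial(self, donor: int, phase: int) -> str:
        """Bases of the partially consumed codon: the last `phase` exonic
        bases before the donor."""
        return self.seq[donor - phase : donor] if phase else ""

    def _segment_has_stop(self, partial: str, pos: int, end: int) -> bool:
        """Any complete in-frame stop in partial + seq[pos:end]?"""
        s = partial + self.seq[pos:end]
        for i in range(0, len(s) - 2, 3):
            if s[i : i + 3] in STOP_CODONS:
                return True
        return False

    def _terminates_at_annotated_stop(self, partial: str, pos: int) -> bool:
        """Scan downstream of ``pos``: does the first in-frame stop coincide
        with an annotated stop codon? A stop codon split across the last
        junction cannot match a (contiguous) annotated codon."""
        phase = len(partial)
        s = partial + self.seq[pos : self.scan_limit]
        for i in range(0, len(s) - 2, 3):
            if s[i : i + 3] in STOP_CODONS:
                return i >= phase and (pos + i - phase) in self.stops
        return False

    def run(self, junctions: list[Junction]) -> set[Junction]:
        """Return the subset of ``junctions`` on at least one PTC-free
        START->STOP path."""
        span = self.gene.end - self.gene.start
        oriented = []
        for j in sorted(set(junctions)):
            a, b = self.orient_junction(j)
            if 0 <= a < b <= span:
                oriented.append((a, b, j))
        oriented.sort()
        n = len(oriented)

        # state key: (junction index, phase); start states: (START, start offset)
        junc_sets: dict[tuple, set[int]] = {}
        preds: dict[tuple, set[tuple]] = {}
        completed: set[tuple] = set()
        queue: deque[tuple] = deque()

        for s in self.starts:
            key = (self.START, s)
            junc_sets[key] = set()
            preds[key] = set()
            queue.append(key)

        while queue:
            key = queue.popleft()
            self.expansions += 1
            if key[0] == self.START:
                pos, phase = key[1], 0
                partial = ""
            else:
                a, b, _ = oriented[key[0]]
                phase = key[1]
                pos = b
                partial = self._partial(a, phase)
            # step IV: can this state terminate at an annotated stop?
            if self._terminates_at_annotated_stop(partial, pos):
                completed.add(key)
            # step V: extend with every reachable junction (independent of IV,
            # so alternative last exons are explored)
            for idx in range(n):
                a2, b2, _ = oriented[idx]
                if a2 < pos:
                    continue
                if a2 - pos > self.max_exon_length:
                    break  # oriented is donor-sorted
                # step II: a PTC in the intervening exonic segment kills the path
                if self._segment_has_stop(partial, pos, a2):
                    continue
                phase2 = (phase + (a2 - pos)) % 3
                key2 = (idx, phase2)
                if key2 in junc_sets:
                    # step III: seen state — merge junctions, do not re-expand
                    junc_sets[key2] |= junc_sets[key] | {idx}
                    preds[key2].add(key)
                else:
                    junc_sets[key2] = junc_sets[key] | {idx}
                    preds[key2] = {key}
                    queue.append(key2)

        # steps VII/VIII: a state from which a completed state is reachable has
        # all its accumulated junctions on some productive path (reverse
        # reachability over predecessor edges)
        frontier = deque(completed)
        productive_states = set(completed)
        while frontier:
            k = frontier.popleft()
            for p in preds.get(k, ()):
                if p not in productive_states:
                    productive_states.add(p)
                    frontier.append(p)
        productive_idx: set[int] = set()
        for k in productive_states:
            productive_idx |= junc_sets[k]
        return {oriented[i][2] for i in productive_idx}


def classify_gene(
    gene: GeneModel,
    junctions: list[Junction],
    genome: GenomeSequence,
    max_exon_length: int = DEFAULT_MAX_EXON_LENGTH,
    max_junctions_per_gene: int = DEFAULT_MAX_JUNCTIONS_PER_GENE,
) -> dict[Junction, bool]:
    """Classify junctions against one gene.

    The observed junctions are merged with the gene's annotated
    productive junctions (a junction is productive if it can combine
    with other observed *or annotated productive* junctions to span
    START to STOP), the memoized BFS is run, and each observed junction
    maps to True (productive) or False.
    """
    if not gene.classifiable:
        raise GeneSkipped(f"gene {gene.gene_id} lacks start or stop codons")
    merged = set(junctions)
    for s, e in gene.annotated_productive_junctions:
        merged.add(Junction(gene.chrom, s, e, gene.strand))
    if len(merged) > max_junctions_per_gene:
        raise GeneSkipped(
            f"gene {gene.gene_id} has {len(merged)} junctions "
            f"(cap {max_junctions_per_gene})"
        )
    search = _GeneSearch(gene, genome, max_exon_length)
    productive = search.run(sorted(merged))
    productive_keys = {(j.start, j.end) for j in productive}
    return {j: (j.start, j.end) in productive_keys for j in junctions}


def classify_all(
    genes: list[GeneModel],
    junctions_or_clusters,
    genome: GenomeSequence,
    max_exon_length: int = DEFAULT_MAX_EXON_LENGTH,
    max_junctions_per_gene: int = DEFAULT_MAX_JUNCTIONS_PER_GENE,
) -> pd.DataFrame:
    """Classify every junction against all overlapping genes.

    Accepts a list of clusters or a plain junction list. bit1 is an OR
    over overlapping classifiable genes; bit0 requires the junction to be
    UTR-ambiguous in all of them; bit2/bit3 come from annotated
    transcript membership. Junctions overlapping no classifiable gene
    get category UTR.
    """
    if junctions_or_clusters and isinstance(junctions_or_clusters[0], IntronCluster):
        cluster_of = {
            j: c.cluster_id for c in junctions_or_clusters for j in c.junctions
        }
        junctions = sorted(cluster_of)
    else:
        junctions = sorted(set(junctions_or_clusters))
        cluster_of = {j: "." for j in junctions}

    index = GeneIndex(genes)
    known_chroms = {g.chrom for g in genes}
    ann: dict[str, set] = {}
    ann_prod: dict[str, set] = {}
    for g in genes:
        ann.setdefault(g.chrom, set()).update(
            (s, e, g.strand) for (s, e) in g.annotated_junctions
        )
        ann_prod.setdefault(g.chrom, set()).update(
            (s, e, g.strand) for (s, e) in g.annotated_productive_junctions
        )

    # per-gene productive calls, computed once per gene over its junctions
    orf_calls: dict[tuple, dict[Junction, bool]] = {}
    warned_chroms = set()
    for g in genes:
        if not g.classifiable:
            continue
        if g.chrom not in genome:
            if g.chrom not in warned_chroms:
                log.warning("chromosome %s absent from genome; genes skipped", g.chrom)
                warned_chroms.add(g.chrom)
            continue
        overlapping = [
            j
            for j in junctions
            if j.chrom == g.chrom
            and j.start < g.end
            and j.end > g.start
            and (j.strand == "." or j.strand == g.strand)
        ]
        try:
            orf_calls[(g.chrom, g.start, g.gene_id)] = classify_gene(
                g, overlapping, genome, max_exon_length, max_junctions_per_gene
            )
        except GeneSkipped as e:
            log.warning("%s", e)

    rows = []
    for j in junctions:
        if j.chrom not in known_chroms and j.chrom not in genome:
            log.warning("junction %s on unknown chromosome; unclassified", j.name())
        genes_here = [
            g
            for g in index.overlapping(j.chrom, j.start, j.end)
            if j.strand == "." or g.strand == j.strand
        ]
        classifiable = [g for g in genes_here if g.classifiable]
        matchable = lambda table: any(
            (j.start, j.end, st) in table.get(j.chrom, set())
            for st in (("+", "-") if j.strand == "." else (j.strand,))
        )
        is_annot = matchable(ann)
        is_prod_annot = matchable(ann_prod)
        if classifiable:
            utr = all(is_utr_junction(j, g) for g in classifiable)
            prod = any(
                orf_calls.get((g.chrom, g.start, g.gene_id), {}).get(j, False)
                for g in classifiable
            )
            rec = assemble_flags(j, utr, prod, is_annot, is_prod_annot)
            category = rec.category
        else:
            rec = assemble_flags(j, False, False, is_annot, is_prod_annot)
            category = categorize(rec.flag, in_gene=False)
        rows.append(
            {
                "chrom": j.chrom,
                "start": j.start,
                "end": j.end,
                "strand": j.strand,
                "cluster": cluster_of.get(j, "."),
                "gene_ids": ",".join(g.gene_id for g in classifiable) or ".",
                "utr": rec.utr,
                "orf_productive": rec.orf_productive,
                "is_annotated": rec.is_annotated,
                "is_productive_annotated": rec.is_productive_annotated,
                "flag": rec.flag,
                "category": category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand", "cluster", "gene_ids", "utr",
            "orf_productive", "is_annotated", "is_productive_annotated", "flag",
            "category",
        ],
    )
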