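"""NMD-efficiency rule annotation for unproductive junctions.

An unproductive junction is substituted into every compatible annotated
protein-coding transcript (compatible = shares its donor or acceptor
with one of the transcript's splice sites). For each substitution that
induces a PTC, three rule metrics are computed and aggregated across
transcripts:

1. 50-nt rule — spliced-nucleotide distance from the PTC to the last
   exon-exon junction of the modified transcript (maximum over
   transcripts). PTCs in the final exon, or closer than 50 nt to the
   last junction, typically escape NMD.
2. Median number of introns upstream and downstream of the PTC.
3. Modal length of the PTC-containing exon; PTCs inside long exons
   (>= 407 nt) are inefficiently degraded.

Distances are measured in spliced-mRNA nucleotides, the quantity the
exon-junction-complex mechanism actually senses.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass

import pandas as pd

from .genome import GeneModel, GenomeSequence, TranscriptModel, fetch_spliced_sequence
from .junctions import Junction

log = logging.getLogger(__name__)

LONG_EXON_THRESHOLD = 407
ESCAPE_DISTANCE_NT = 50

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class NMDAnnotation:
    junction: Junction
    max_distance_to_last_junction: float  # NaN when untestable or all final-exon
    ptc_in_final_exon: bool
    median_introns_upstream: float
    median_introns_downstream: float
    modal_exon_length: float
    n_transcripts: int

    @property
    def testable(self) -> bool:
        return self.n_transcripts > 0

    @property
    def escapes_50nt(self) -> bool | None:
        """True when the PTC is expected to escape NMD by the 50-nt rule."""
        if not self.testable:
            return None
        if math.isnan(self.max_distance_to_last_junction):
            return self.ptc_in_final_exon
        return self.max_distance_to_last_junction < ESCAPE_DISTANCE_NT

    @property
    def long_exon(self) -> bool | None:
        if not self.testable or math.isnan(self.modal_exon_length):
            return None
        return self.modal_exon_length >= LONG_EXON_THRESHOLD


def find_compatible_transcripts(
    junction: Junction, gene: GeneModel
) -> list[TranscriptModel]:
    """Protein-coding transcripts sharing the junction's donor or acceptor."""
    out = []
    for t in gene.transcripts:
        if not t.is_productive_type:
            continue
        starts = {s for s, _ in t.junctions}
        ends = {e for _, e in t.junctions}
        if junction.start in starts or junction.end in ends:
            out.append(t)
    return out


def substitute_junction(
    transcript: TranscriptModel, junction: Junction
) -> list[tuple[int, int]] | None:
    """Replace the matched native intron(s) with the query junction's intron.

    The exon boundary at the non-matching end is moved to the query
    coordinate; exons fully contained in the query intron are removed
    (exon-skipping junctions). Returns None when the substitution would
    create an empty or inverted exon, or when the non-matching end falls
    inside a native intron with no exon to anchor to.
    """
    exons = transcript.exons
    qs, qe = junction.start, junction.end
    starts = {s for s, _ in transcript.junctions}
    ends = {e for _, e in transcript.junctions}
    if qs not in starts and qe not in ends:
        return None

    left_idx = [i for i, (s, _) in enumerate(exons) if s < qs]
    right_idx = [i for i, (_, e) in enumerate(exons) if e > qe]
    if not left_idx or not right_idx or left_idx[-1] >= right_idx[0]:
        return None  # junction dangles off the transcript or nests in one exon
    # exons fully swallowed by the query intron are only legitimate for a
    # skip junction whose BOTH ends sit on native splice sites; a single
    # matched end may merely move the adjacent exon boundary
    swallowed = any(qs <= s and e <= qe for s, e in exons)
    if swallowed and not (qs in starts and qe in ends):
        return None
    # move the boundary at each (possibly non-matching) end to the query
    # coordinate
    left = [exons[i] for i in left_idx]
    right = [exons[i] for i in right_idx]
    left[-1] = (left[-1][0], qs)
    right[0] = (qe, right[0][1])
    chain = left + right
    if any(e - s <= 0 for s, e in chain):
        return None
    if any(chain[i][1] >= chain[i + 1][0] for i in range(len(chain) - 1)):
        return None
    return chain


def _spliced_offset(chain, strand: str, pos: int) -> int | None:
    """Spliced-mRNA offset (transcription order) of genomic base ``pos``."""
    if strand == "-":
        chain = [(s, e) for s, e in reversed(chain)]
    off = 0
    for s, e in chain:
        if s <= pos < e:
            if strand == "-":
                return off + (e - 1 - pos)
            return off + (pos - s)
        off += e - s
    return None


def locate_ptc(
    chain: list[tuple[int, int]],
    transcript: TranscriptModel,
    gene: GeneModel,
    genome: GenomeSequence,
) -> int | None:
    """Spliced offset of the first in-frame stop before the annotated stop.

    Translation starts at the transcript's annotated start codon; None
    when translation reaches the annotated stop first (or the start
    codon was spliced out by the substitution).
    """
    start_codon = transcript.start_codon
    stop_codon = transcript.stop_codon
    if start_codon is None or stop_codon is None:
        return None
    start_off = _spliced_offset(chain, gene.strand, start_codon)
    if start_off is None:
        log.debug("start codon of %s spliced out", transcript.transcript_id)
        return None
    stop_off = _spliced_offset(chain, gene.strand, stop_codon)
    mrna = fetch_spliced_sequence(genome, chain, gene.strand, gene.chrom)
    for i in range(start_off, len(mrna) - 2, 3):
        if mrna[i : i + 3] in STOP_CODONS:
            if stop_off is not None and i >= stop_off:
                return None  # reached (or passed) the annotated stop
            return i
    return None


def _lower_median(values) -> float:
    return float(statistics.median_low(values))


def _smallest_mode(values) -> float:
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    return float(min(v for v, c in counts.items() if c == best))


def annotate_nmd_rules(
    junction: Junction, gene: GeneModel, genome: GenomeSequence
) -> NMDAnnotation:
    """Compute the three NMD-rule metrics for one unproductive junction.

    Per transcript: substitute, locate the induced PTC, and measure (a)
    spliced distance from the PTC to the last exon-exon junction, (b)
    introns up/downstream of the PTC, (c) PTC-exon length. Aggregate as
    max (a), lower median (b), smallest mode (c). Transcripts without an
    induced PTC contribute nothing; no contributing transcript yields an
    all-missing annotation.
    """
    distances: list[int] = []
    final_exon = False
    ups: list[int] = []
    downs: list[int] = []
    exon_lens: list[int] = []
    n_used = 0
    for t in find_compatible_transcripts(junction, gene):
        chain = substitute_junction(t, junction)
        if chain is None or len(chain) < 2:
            continue
        ptc = locate_ptc(chain, t, gene, genome)
        if ptc is None:
            continue
        n_used += 1
        t_chain = chain if gene.strand != "-" else [(s, e) for s, e in reversed(chain)]
        lens = [e - s for s, e in t_chain]
        # exon index containing the PTC, in transcription order
        cum = 0
        idx = len(lens) - 1
        for k, L in enumerate(lens):
            if cum <= ptc < cum + L:
                idx = k
                break
            cum += L
        ups.append(idx)
        downs.append(len(lens) - 1 - idx)
        exon_lens.append(lens[idx])
        last_junction_off = sum(lens[:-1])
        if idx == len(lens) - 1:
            final_exon = True
        else:
            distances.append(last_junction_off - ptc)
    if n_used == 0:
        return NMDAnnotation(
            junction, float("nan"), False, float("nan"), float("nan"), float("nan"), 0
        )
    return NMDAnnotation(
        junction,
        float(max(distances)) if distances else float("nan"),
        final_exon,
        _lower_median(ups),
        _lower_median(downs),
        _smallest_mode(exon_lens),
        n_used,
    )


def annotate_table(
    classification: pd.DataFrame,
    genes: list[GeneModel],
    genome: GenomeSequence,
) -> pd.DataFrame:
    """NMD-rule annotations for every unproductive junction in a
    classification table (UTR-flagged junctions are excluded)."""
    from .genome import GeneIndex

    index = GeneIndex(genes)
    rows = []
    for _, r in classification.iterrows():
        if r["category"] != "unproductive":
            continue
        j = Junction(r["chrom"], int(r["start"]), int(r["end"]), r["strand"])
        best: NMDAnnotation | None = None
        for g in index.overlapping(j.chrom, j.start, j.end):
            if j.strand not in (".", g.strand):
                continue
            a = annotate_nmd_rules(j, g, genome)
            if a.testable and (best is None or a.n_transcripts > best.n_transcripts):
                best = a
        a = best or NMDAnnotation(
            j, float("nan"), False, float("nan"), float("nan"), float("nan"), 0
        )
        rows.append(
            {
                "chrom": j.chrom,
                "start": j.start,
                "end": j.end,
                "strand": j.strand,
                "max_distance_to_last_junction": a.max_distance_to_last_junction,
                "ptc_in_final_exon": a.ptc_in_final_exon,
                "median_introns_upstream": a.median_introns_upstream,
                "median_introns_downstream": a.median_introns_downstream,
                "modal_exon_length": a.modal_exon_length,
                "escapes_50nt": a.escapes_50nt,
                "long_exon": a.long_exon,
                "n_transcripts": a.n_transcripts,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand", "max_distance_to_last_junction",
            "ptc_in_final_exon", "median_introns_upstream",
            "median_introns_downstream", "modal_exon_length", "escapes_50nt",
            "long_exon", "n_transcripts",
        ],
    )
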