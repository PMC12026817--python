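"""Synthetic loci with known productive/unproductive truth, plus an
exhaustive path-enumeration oracle and multinomial count simulation.

A toy locus is a single protein-coding gene: 5'UTR, a chain of coding
exons (first codon ATG, last codon TAA, interior codons sampled from the
61 sense codons so the canonical frame is stop-free), introns, and a
3'UTR. Planted event classes mirror the ones seen in real data:

- poison exon: a cassette exon inside an intron carrying an in-frame
  stop under inclusion — both inclusion junctions are unproductive, the
  skipping (canonical) junction productive;
- frame-shifting exon skip: a skip junction over an exon whose length is
  not a multiple of 3, with a stop planted in the shifted frame
  downstream — the skip junction is unproductive;
- in-frame exon skip: skip over a length-3k exon (productive), with the
  bases flanking the skip boundary patched to C so no chimeric stop can
  arise (stop codons contain no C);
- 3'UTR intron: a junction entirely downstream of the stop codon
  (UTR-ambiguous).

Every intron begins with the motif TAACTAACTAA, which contains a stop
codon in all three frames: any read-through path that enters an intron
is guaranteed to terminate, so planted truth labels cannot be silently
broken by a chance stop-free intron.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import reverse_complement

from .genome import GeneModel, GenomeSequence, TranscriptModel, gene_models_to_gtf
from .junctions import Junction, SampleJunctionCounts, write_junction_bed

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
#: stop codon in all three frames; planted at the start of every intron
INTRON_KILL_MOTIF = "TAACTAACTAA"


class InfeasibleSpec(ValueError):
    pass


@dataclass
class GeneSpec:
    """Blueprint of one synthetic gene locus (plus-strand design, mirrored
    genome-wide if ``strand`` is '-')."""

    exon_coding: tuple[int, ...] = (60, 90, 75)  # coding nt per exon, sum % 3 == 0
    intron_lengths: tuple[int, ...] = (80, 80)
    strand: str = "+"
    utr5: int = 60
    utr3: int = 60
    flank: int = 50
    # poison exon inserted into intron ``after_exon``: (after_exon, length, off5, off3)
    poison: tuple[int, int, int, int] | None = None
    skip_exon: int | None = None  # index of a skippable interior exon
    utr3_intron: tuple[int, int] | None = None  # (offset into 3'UTR, length)
    seed: int = 0

    def validate(self):
        if len(self.exon_coding) < 2:
            raise InfeasibleSpec("need at least 2 exons")
        if len(self.intron_lengths) != len(self.exon_coding) - 1:
            raise InfeasibleSpec("need n_exons - 1 introns")
        if any(x < 3 for x in self.exon_coding):
            raise InfeasibleSpec("every exon needs >= 3 coding nt")
        if sum(self.exon_coding) % 3:
            raise InfeasibleSpec("total coding length must be divisible by 3")
        if sum(self.exon_coding) < 6:
            raise InfeasibleSpec("need room for ATG and stop")
        min_intron = len(INTRON_KILL_MOTIF) + 3
        if any(x < min_intron for x in self.intron_lengths):
            raise InfeasibleSpec(f"introns must be >= {min_intron} nt")
        if self.poison is not None:
            k, plen, off5, off3 = self.poison
            if not 0 <= k < len(self.intron_lengths):
                raise InfeasibleSpec("poison exon must sit inside an existing intron")
            if off5 < min_intron or off3 < min_intron:
                raise InfeasibleSpec("poison flanking intron parts too short")
            if off5 + plen + off3 > self.intron_lengths[k]:
                raise InfeasibleSpec("poison exon does not fit in its intron")
            if plen < 9:
                raise InfeasibleSpec("poison exon too short to host an in-frame stop")
        if self.skip_exon is not None:
            k = self.skip_exon
            if not 1 <= k <= len(self.exon_coding) - 2:
                raise InfeasibleSpec("only interior exons can be skipped")
            if self.exon_coding[k] % 3 == 0 and (
                self.exon_coding[k - 1] < 5 or self.exon_coding[k + 1] < 5
            ):
                raise InfeasibleSpec("in-frame skip needs >= 5 coding nt in flanking exons")
            if self.exon_coding[k] % 3 != 0 and self.exon_coding[k + 1] < 12:
                raise InfeasibleSpec("frame-shift skip needs >= 12 coding nt downstream")
        if self.utr3_intron is not None:
            off, ln = self.utr3_intron
            if off < 1 or ln < 1 or off + ln >= self.utr3:
                raise InfeasibleSpec("3'UTR intron must lie strictly inside the 3'UTR")


@dataclass
class ToyLocus:
    chrom: str
    fasta: str
    gtf: str
    truth: dict[Junction, str]  # junction -> productive / unproductive / UTR
    genome: GenomeSequence
    gene: GeneModel
    junctions: list[Junction] = field(default_factory=list)

    def write(self, out_dir) -> tuple[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        fasta_path = os.path.join(out_dir, f"{self.chrom}.fa")
        gtf_path = os.path.join(out_dir, f"{self.chrom}.gtf")
        with open(fasta_path, "w") as fh:
            fh.write(self.fasta)
        with open(gtf_path, "w") as fh:
            fh.write(self.gtf)
        return fasta_path, gtf_path


def _random_nt(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_sense(rng, n_codons: int) -> str:
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


def _intron_seq(rng, n: int) -> str:
    return INTRON_KILL_MOTIF + _random_nt(rng, n - len(INTRON_KILL_MOTIF))


def make_toy_locus(spec: GeneSpec, chrom: str = "chrT") -> ToyLocus:
    """Build genome FASTA, GTF annotation, and the truth table for one spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_exons = len(spec.exon_coding)

    cds = list("ATG" + _random_sense(rng, sum(spec.exon_coding) // 3 - 2) + "TAA")
    bounds = np.cumsum((0,) + spec.exon_coding)

    truth: dict[Junction, str] = {}

    if spec.skip_exon is not None:
        k = spec.skip_exon
        shift = spec.exon_coding[k] % 3
        if shift == 0:
            # guard the chimeric codon: stops contain no C
            for p in (bounds[k] - 2, bounds[k] - 1, bounds[k + 1], bounds[k + 1] + 1):
                cds[p] = "C"
        else:
            # plant a stop in the shifted frame inside the downstream exon
            lo = bounds[k + 1] + 3
            hi = bounds[k + 2] - 5
            o = next((o for o in range(lo, hi) if o % 3 == shift), None)
            if o is None:
                raise InfeasibleSpec("no room to plant frame-shift stop")
            cds[o : o + 3] = list("TAA")
            if shift == 1:
                cds[o - 1] = "C"  # canonical codon CTA
            else:
                cds[o - 2 : o] = list("CC")  # canonical codon CC?
    cds = "".join(cds)
    chunks = [cds[bounds[i] : bounds[i + 1]] for i in range(n_exons)]

    # --- assemble the chromosome (plus-strand layout) -------------------
    parts: list[str] = [_random_nt(rng, spec.flank)]
    pos = spec.flank
    exon_iv: list[tuple[int, int]] = []
    poison_iv = None

    def push(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        iv = (pos, pos + len(seq))
        pos += len(seq)
        return iv

    utr3_seq = _random_nt(rng, spec.utr3)
    for i, chunk in enumerate(chunks):
        if i == 0:
            exon_iv.append(push(_random_nt(rng, spec.utr5) + chunk))
        elif i == n_exons - 1:
            exon_iv.append(push(chunk + utr3_seq))
        else:
            exon_iv.append(push(chunk))
        if i < n_exons - 1:
            if spec.poison is not None and spec.poison[0] == i:
                k, plen, off5, off3 = spec.poison
                phase = int(bounds[i + 1]) % 3  # bases consumed at poison entry
                c = (3 - phase) % 3 + 3
                pseq = list(_random_nt(rng, plen))
                pseq[c : c + 3] = list("TAA")
                push(_intron_seq(rng, off5))
                poison_iv = push("".join(pseq))
                push(_intron_seq(rng, off3))
            else:
                push(_intron_seq(rng, spec.intron_lengths[i]))
    parts.append(_random_nt(rng, spec.flank))
    chrom_seq = "".join(parts)
    L = len(chrom_seq)

    # --- junctions and truth -------------------------------------------
    canonical = [
        Junction(chrom, exon_iv[i][1], exon_iv[i + 1][0], spec.strand)
        for i in range(n_exons - 1)
    ]
    junctions = list(canonical)
    for j in canonical:
        truth[j] = "productive"
    if spec.poison is not None:
        k = spec.poison[0]
        j_in5 = Junction(chrom, exon_iv[k][1], poison_iv[0], spec.strand)
        j_in3 = Junction(chrom, poison_iv[1], exon_iv[k + 1][0], spec.strand)
        junctions.extend([j_in5, j_in3])
        truth[j_in5] = truth[j_in3] = "unproductive"
    if spec.skip_exon is not None:
        k = spec.skip_exon
        j_skip = Junction(chrom, exon_iv[k - 1][1], exon_iv[k + 1][0], spec.strand)
        junctions.append(j_skip)
        truth[j_skip] = "productive" if spec.exon_coding[k] % 3 == 0 else "unproductive"
    if spec.utr3_intron is not None:
        off, ln = spec.utr3_intron
        u0 = exon_iv[-1][1] - spec.utr3
        j_utr = Junction(chrom, u0 + off, u0 + off + ln, spec.strand)
        junctions.append(j_utr)
        truth[j_utr] = "UTR"

    if spec.strand == "-":
        # mirror the whole plus-strand design; codon positions are
        # re-derived from spliced offsets in _finalize
        chrom_seq = reverse_complement(chrom_seq)
        exon_iv = sorted((L - e, L - s) for s, e in exon_iv)
        remap = {j: Junction(chrom, L - j.end, L - j.start, "-") for j in junctions}
        junctions = [remap[j] for j in junctions]
        truth = {remap[j]: c for j, c in truth.items()}

    return _finalize(spec, chrom, chrom_seq, exon_iv, junctions, truth, L)


def _finalize(spec, chrom, chrom_seq, exon_iv, junctions, truth, L) -> ToyLocus:
    """Derive codon positions from the assembled sequence and emit outputs."""
    strand = spec.strand
    # spliced CDS coordinates: UTR5 then CDS then UTR3 in transcription order
    if strand == "-":
        t_exons = sorted(exon_iv, key=lambda iv: -iv[0])
    else:
        t_exons = exon_iv
    cds_len = sum(spec.exon_coding)
    # transcription-order offset of the start codon within the spliced mRNA
    start_off = spec.utr5

    def spliced_to_genomic(off: int) -> int:
        rem = off
        for s, e in t_exons:
            n = e - s
            if rem < n:
                return (s + rem) if strand != "-" else (e - 1 - rem)
            rem -= n
        raise AssertionError("offset beyond mRNA")

    start_codon = spliced_to_genomic(start_off)
    stop_codon = spliced_to_genomic(start_off + cds_len - 3)

    transcript = TranscriptModel(
        transcript_id="TX1",
        transcript_type="protein_coding",
        exons=sorted(exon_iv),
        start_codon=start_codon,
        stop_codon=stop_codon,
    )
    gene = GeneModel(
        gene_id="GENE1",
        chrom=chrom,
        strand=strand,
        start=min(s for s, _ in exon_iv),
        end=max(e for _, e in exon_iv),
        start_codons={start_codon},
        stop_codons={stop_codon},
        transcripts=[transcript],
    )
    genome = GenomeSequence({chrom: chrom_seq})

    fasta = f">{chrom}\n" + "\n".join(
        chrom_seq[i : i + 60] for i in range(0, len(chrom_seq), 60)
    ) + "\n"
    gtf = gene_models_to_gtf([gene])

    return ToyLocus(chrom, fasta, gtf, truth, genome, gene, sorted(junctions))


def brute_force_classify(
    gene: GeneModel,
    junctions: list[Junction],
    genome: GenomeSequence,
    max_exon_length: int = 5000,
    max_paths: int = 500_000,
) -> dict[Junction, bool]:
    """Exhaustive oracle: enumerate every coordinate-increasing junction
    sequence from every start codon, translate the implied spliced
    sequence character by character, and accept paths whose first
    in-frame stop is a contiguous annotated stop codon in the terminal
    segment. A junction is productive iff it lies on >= 1 accepted path.

    Shares no path/translation logic with the breadth-first classifier.
    """
    if not gene.classifiable:
        raise ValueError(f"gene {gene.gene_id} not classifiable")
    gs, ge = gene.start, gene.end
    strand = gene.strand
    seq = genome.fetch(gene.chrom, gs, ge, "+")
    if strand == "-":
        seq = reverse_complement(seq)

    def opoint(p: int) -> int:
        return p - gs if strand != "-" else (ge - 1) - p

    def ointer(a: int, b: int) -> tuple[int, int]:
        return (a - gs, b - gs) if strand != "-" else (ge - b, ge - a)

    ojuncs = sorted({ointer(j.start, j.end) for j in junctions if j.start >= gs and j.end <= ge})
    starts = sorted(opoint(p) for p in gene.start_codons)
    stops = {opoint(p) for p in gene.stop_codons}
    limit = min(max(stops) + 3, len(seq))

    productive: set[tuple[int, int]] = set()
    n_paths = 0

    def accept(start: int, path: list[tuple[int, int]]) -> bool:
        segs = []
        p = start
        for a, b in path:
            segs.append((p, a))
            p = b
        terminal_start = p
        segs.append((p, limit))
        spliced = "".join(seq[x:y] for x, y in segs)
        posmap = [g for x, y in segs for g in range(x, y)]
        for i in range(0, len(spliced) - 2, 3):
            if spliced[i : i + 3] in STOP_CODONS:
                g0 = posmap[i]
                contiguous = posmap[i + 1] == g0 + 1 and posmap[i + 2] == g0 + 2
                ok = contiguous and g0 in stops and g0 >= terminal_start
                if ok:
                    # spliced CDS length from start codon through stop must be
                    # divisible by 3 (the scan walks whole codons from offset 0)
                    assert i % 3 == 0 and (i + 3) <= len(spliced)
                return ok
        return False

    def explore(start: int, pos: int, path: list[tuple[int, int]]):
        nonlocal n_paths
        n_paths += 1
        if n_paths > max_paths:
            raise RuntimeError("brute-force enumeration budget exceeded")
        if accept(start, path):
            productive.update(path)
        for a, b in ojuncs:
            if a >= pos and a - pos <= max_exon_length:
                explore(start, b, path + [(a, b)])

    for s in starts:
        explore(s, s, [])

    return {j: ointer(j.start, j.end) in productive for j in junctions}


def simulate_counts(
    clusters: list[tuple[list[Junction], list[float]]],
    depth: int,
    n_samples: int,
    seed: int,
    out_dir=None,
) -> list[SampleJunctionCounts]:
    """Multinomial junction counts per cluster per sample at planted PSI.

    ``clusters`` pairs each junction group with its PSI vector (must sum
    to 1 within the group). Optionally writes one BED file per sample.
    """
    rng = np.random.default_rng(seed)
    for js, psi in clusters:
        if len(js) != len(psi):
            raise ValueError("psi vector length must match junction count")
        if abs(sum(psi) - 1.0) > 1e-8:
            raise ValueError("planted PSI values must sum to 1 within a cluster")
    if depth == 0:
        log.warning("depth 0: simulating all-zero counts")
    samples = []
    for i in range(n_samples):
        counts: dict[Junction, int] = {}
        for js, psi in clusters:
            draws = rng.multinomial(depth, psi)
            for j, c in zip(js, draws):
                counts[j] = counts.get(j, 0) + int(c)
        samples.append(SampleJunctionCounts(f"sample{i:03d}", counts))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for s in samples:
            write_junction_bed(s, os.path.join(out_dir, f"{s.sample_id}.junc"))
    return samples


def random_gene_spec(rng: np.random.Generator) -> GeneSpec:
    """A random feasible GeneSpec for stress tests (truth via the oracle)."""
    n_exons = int(rng.integers(2, 5))
    exon_coding = [int(rng.integers(2, 20)) * 3 for _ in range(n_exons)]
    # random per-exon phase wiggle while keeping the total divisible by 3
    wiggle = int(rng.integers(0, 3))
    if n_exons >= 2 and wiggle:
        exon_coding[0] += wiggle
        exon_coding[-1] += 3 - wiggle
    introns = tuple(int(rng.integers(20, 120)) for _ in range(n_exons - 1))
    spec = GeneSpec(
        exon_coding=tuple(exon_coding),
        intron_lengths=introns,
        strand="+" if rng.random() < 0.5 else "-",
        utr5=int(rng.integers(20, 80)),
        utr3=int(rng.integers(20, 80)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    if n_exons >= 3 and rng.random() < 0.4:
        k = int(rng.integers(0, n_exons - 1))
        if introns[k] >= 70:
            spec.poison = (k, int(rng.integers(12, 30)), 20, 20)
    if n_exons >= 3 and spec.poison is None and rng.random() < 0.4:
        k = int(rng.integers(1, n_exons - 1))
        try:
            trial = GeneSpec(
                exon_coding=spec.exon_coding,
                intron_lengths=spec.intron_lengths,
                strand=spec.strand,
                utr5=spec.utr5,
                utr3=spec.utr3,
                skip_exon=k,
                seed=spec.seed,
            )
            trial.validate()
            spec = trial
        except InfeasibleSpec:
            pass
    return spec


def random_extra_junctions(
    rng: np.random.Generator, gene: GeneModel, n: int
) -> list[Junction]:
    """Random intron intervals within the gene span (arbitrary coordinates)."""
    out = []
    span = gene.end - gene.start
    for _ in range(n):
        a = int(rng.integers(0, span - 2))
        b = int(rng.integers(a + 1, min(a + 400, span)))
        out.append(Junction(gene.chrom, gene.start + a, gene.start + b, gene.strand))
    return out
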