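"""NMD-rule tests on hand-countable fixtures plus a from-scratch
per-transcript oracle for the aggregated metrics."""

import math

import pytest

from spliceclass.genome import GeneModel, GenomeSequence, TranscriptModel
from spliceclass.junctions import Junction
from spliceclass.nmd import (
    ESCAPE_DISTANCE_NT,
    LONG_EXON_THRESHOLD,
    annotate_nmd_rules,
    find_compatible_transcripts,
    locate_ptc,
    substitute_junction,
)

STOPS = {"TAA", "TAG", "TGA"}


def _oracle_substitute(tx, a, b):
    """Case-by-case rebuild of the substituted chain, from scratch."""
    exons, introns = tx.exons, tx.junctions
    donor = [i for i, (s, _) in enumerate(introns) if s == a]
    acc = [i for i, (_, e) in enumerate(introns) if e == b]
    if donor and acc:  # pure intron replacement / exon skip
        i, k = donor[0], acc[0]
        return exons[: i + 1] + exons[k + 1 :] if i <= k else None
    if donor:  # acceptor side moves within the matched intron or next exon
        i = donor[0]
        nxt = exons[i + 1]
        if not a < b < nxt[1]:
            return None
        return exons[: i + 1] + [(b, nxt[1])] + exons[i + 2 :]
    if acc:  # donor side moves within the matched intron or previous exon
        i = acc[0]
        prv = exons[i]
        if not prv[0] < a < b:
            return None
        return exons[:i] + [(prv[0], a)] + exons[i + 1 :]
    return None


class TestCompatibility:
    def test_donor_match_only(self, nmd_gene):
        gene, _ = nmd_gene
        assert find_compatible_transcripts(Junction("chrN", 100, 150, "+"), gene) == [
            gene.transcripts[0]
        ]

    def test_no_site_match(self, nmd_gene):
        gene, _ = nmd_gene
        assert find_compatible_transcripts(Junction("chrN", 101, 150, "+"), gene) == []

    def test_matches_naive_site_scan(self, nmd_gene, rng):
        gene, _ = nmd_gene
        all_sites_start = {s for t in gene.transcripts for s, _ in t.junctions}
        all_sites_end = {e for t in gene.transcripts for _, e in t.junctions}
        for _ in range(50):
            a = int(rng.integers(0, 499))
            b = int(rng.integers(a + 1, 500))
            j = Junction("chrN", a, b, "+")
            want = a in all_sites_start or b in all_sites_end
            assert bool(find_compatible_transcripts(j, gene)) == want


class TestSubstitution:
    def test_alternative_acceptor_moves_exon_start(self, nmd_gene):
        gene, _ = nmd_gene
        tx = gene.transcripts[0]
        chain = substitute_junction(tx, Junction("chrN", 100, 250, "+"))
        assert chain == [(0, 100), (250, 300), (400, 500)]

    def test_identity_substitution(self, nmd_gene):
        gene, _ = nmd_gene
        tx = gene.transcripts[0]
        assert substitute_junction(tx, Junction("chrN", 100, 200, "+")) == tx.exons

    def test_alternative_donor_into_intron(self, nmd_gene):
        gene, _ = nmd_gene
        tx = gene.transcripts[0]
        chain = substitute_junction(tx, Junction("chrN", 150, 200, "+"))
        assert chain == [(0, 150), (200, 300), (400, 500)]

    def test_exon_skipping_junction_drops_exon(self, nmd_gene):
        gene, _ = nmd_gene
        tx = gene.transcripts[0]
        chain = substitute_junction(tx, Junction("chrN", 100, 400, "+"))
        assert chain == [(0, 100), (400, 500)]

    def test_swallowing_whole_transcript_end_rejected(self, nmd_gene):
        gene, _ = nmd_gene
        tx = gene.transcripts[0]
        assert substitute_junction(tx, Junction("chrN", 100, 600, "+")) is None

    def test_random_substitutions_match_rebuild_oracle(self, nmd_gene, rng):
        gene, _ = nmd_gene
        tx = gene.transcripts[0]
        intron_starts = {s for s, _ in tx.junctions}
        intron_ends = {e for _, e in tx.junctions}
        for _ in range(100):
            a = int(rng.integers(0, 499))
            b = int(rng.integers(a + 1, 500))
            j = Junction("chrN", a, b, "+")
            if a not in intron_starts and b not in intron_ends:
                continue
            got = substitute_junction(tx, j)
            assert got == _oracle_substitute(tx, a, b), j


class TestLocatePTC:
    def test_poison_inclusion_chain_has_ptc(self, poison_locus):
        gene = poison_locus.gene
        tx = gene.transcripts[0]
        j5 = sorted(j for j, c in poison_locus.truth.items() if c == "unproductive")[0]
        chain = substitute_junction(tx, j5)
        assert chain is not None
        assert locate_ptc(chain, tx, gene, poison_locus.genome) is not None

    def test_clean_chain_has_no_ptc(self, nmd_gene):
        gene, genome = nmd_gene
        tx = gene.transcripts[0]
        assert locate_ptc(tx.exons, tx, gene, genome) is None

    def test_matches_codon_by_codon_oracle(self, nmd_gene):
        gene, genome = nmd_gene
        tx = gene.transcripts[0]
        for j in (Junction("chrN", 150, 200, "+"), Junction("chrN", 380, 400, "+")):
            chain = substitute_junction(tx, j)
            got = locate_ptc(chain, tx, gene, genome)
            mrna = "".join(genome.sequences["chrN"][s:e] for s, e in chain)
            # oracle: scan codons from the start codon's spliced offset
            off = 0
            start_off = None
            for s, e in chain:
                if s <= tx.start_codon < e:
                    start_off = off + tx.start_codon - s
                off += e - s
            want = None
            for i in range(start_off, len(mrna) - 2, 3):
                if mrna[i : i + 3] in STOPS:
                    want = i
                    break
            # a stop at/after the annotated stop is not premature
            stop_off = sum(
                e - s for s, e in chain if e <= 488
            ) + (488 - [s for s, e in chain if s <= 488 < e][0])
            if want is not None and want >= stop_off:
                want = None
            assert got == want


class TestAnnotateRules:
    def test_ptc_in_internal_exon_hand_counts(self, nmd_gene):
        gene, genome = nmd_gene
        # retained [100,150): PTC at genomic 120 = spliced 120; chain exon
        # lengths 150/100/100, last junction at 250 -> distance 130
        a = annotate_nmd_rules(Junction("chrN", 150, 200, "+"), gene, genome)
        assert a.testable and a.n_transcripts == 1
        assert a.max_distance_to_last_junction == 130
        assert a.escapes_50nt is False
        assert (a.median_introns_upstream, a.median_introns_downstream) == (0, 2)
        assert a.modal_exon_length == 150
        assert a.long_exon is False

    def test_ptc_between_two_introns_hand_counts(self, nmd_gene):
        gene, genome = nmd_gene
        # retained [300,380): PTC at genomic 310 = spliced 210; chain lengths
        # 100/180/100, last junction at 280 -> distance 70
        a = annotate_nmd_rules(Junction("chrN", 380, 400, "+"), gene, genome)
        assert a.max_distance_to_last_junction == 70
        assert a.escapes_50nt is False
        assert (a.median_introns_upstream, a.median_introns_downstream) == (1, 1)
        assert a.modal_exon_length == 180

    def test_final_exon_ptc(self, poison_locus):
        gene = poison_locus.gene
        j5 = sorted(j for j, c in poison_locus.truth.items() if c == "unproductive")[0]
        a = annotate_nmd_rules(j5, gene, poison_locus.genome)
        assert a.ptc_in_final_exon
        assert a.median_introns_downstream == 0
        assert a.escapes_50nt is True

    def test_untestable_junction_is_all_missing(self, nmd_gene):
        gene, genome = nmd_gene
        a = annotate_nmd_rules(Junction("chrN", 101, 199, "+"), gene, genome)
        assert not a.testable
        assert math.isnan(a.max_distance_to_last_junction)
        assert a.escapes_50nt is None and a.long_exon is None

    def test_aggregation_matches_per_transcript_oracle(self, rng):
        # two transcripts sharing the query donor but with different exon
        # structure; aggregate = max / lower-median / smallest-mode
        seq = (
            "ATG" + "C" * 97  # E1 [0,100)
            + "C" * 82 + "TAA" + "C" * 15  # intron [100,200) with stop at 182
            + "C" * 100  # E2 [200,300)
            + "C" * 100  # intron [300,400)
            + "C" * 88 + "TAA" + "C" * 9  # E3 [400,500)
        )
        genome = GenomeSequence({"c": seq})
        t1 = TranscriptModel(
            "t1", "protein_coding", [(0, 100), (200, 300), (400, 500)], 0, 488
        )
        # t2 lacks the middle intron: [200,500) is one long exon
        t2 = TranscriptModel("t2", "protein_coding", [(0, 100), (200, 500)], 0, 488)
        gene = GeneModel("g", "c", "+", 0, 500, {0}, {488}, [t1, t2])
        # shortened intron [100,180): bases [180,200) become exonic, PTC at 182
        j = Junction("c", 100, 180, "+")
        a = annotate_nmd_rules(j, gene, genome)
        # oracle, recomputed per transcript from first principles
        per_tx = []
        for tx in (t1, t2):
            chain = [(0, 100), (180, tx.exons[1][1])] + tx.exons[2:]
            lens = [e - s for s, e in chain]
            ptc = 100 + (182 - 180)  # spliced offset of genomic 182
            cum, idx = 0, None
            for k, L in enumerate(lens):
                if cum <= ptc < cum + L:
                    idx = k
                    break
                cum += L
            per_tx.append(
                {
                    "dist": sum(lens[:-1]) - ptc if idx < len(lens) - 1 else None,
                    "up": idx,
                    "down": len(lens) - 1 - idx,
                    "exon_len": lens[idx],
                }
            )
        dists = [p["dist"] for p in per_tx if p["dist"] is not None]
        assert a.max_distance_to_last_junction == max(dists)
        ups = sorted(p["up"] for p in per_tx)
        assert a.median_introns_upstream == ups[(len(ups) - 1) // 2]
        assert a.modal_exon_length == min(p["exon_len"] for p in per_tx)  # tie -> smallest
        assert a.n_transcripts == 2

    @pytest.mark.parametrize("exon_len", [405, 406, 407, 408, 409])
    def test_long_exon_flips_exactly_at_threshold(self, exon_len):
        # junction [100,180) extends the 2-exon gene's final exon to exon_len;
        # the PTC lands in that final exon
        base = exon_len - 20
        stop_local = ((100 + base - 3) // 3) * 3 - 100  # in-frame, near exon end
        e2 = list("C" * base)
        e2[stop_local : stop_local + 3] = "TAA"
        seq = (
            "ATG" + "C" * 97
            + "C" * 82 + "TAA" + "C" * 15  # intron [100,200), stop at 182
            + "".join(e2)
        )
        genome = GenomeSequence({"c": seq})
        stop_codon = 200 + stop_local
        tx = TranscriptModel("t", "protein_coding", [(0, 100), (200, 200 + base)], 0, stop_codon)
        gene = GeneModel("g", "c", "+", 0, 200 + base, {0}, {stop_codon}, [tx])
        a = annotate_nmd_rules(Junction("c", 100, 180, "+"), gene, genome)
        assert a.ptc_in_final_exon
        assert a.modal_exon_length == exon_len
        assert a.long_exon is (exon_len >= LONG_EXON_THRESHOLD)
        assert LONG_EXON_THRESHOLD == 407 and ESCAPE_DISTANCE_NT == 50

    def test_aggregates_invariant_to_transcript_order(self, rng):
        seq = (
            "ATG" + "C" * 97
            + "C" * 82 + "TAA" + "C" * 15
            + "C" * 100 + "C" * 100
            + "C" * 88 + "TAA" + "C" * 9
        )
        genome = GenomeSequence({"c": seq})
        t1 = TranscriptModel("t1", "protein_coding", [(0, 100), (200, 300), (400, 500)], 0, 488)
        t2 = TranscriptModel("t2", "protein_coding", [(0, 100), (200, 500)], 0, 488)
        j = Junction("c", 100, 180, "+")
        g12 = GeneModel("g", "c", "+", 0, 500, {0}, {488}, [t1, t2])
        g21 = GeneModel("g", "c", "+", 0, 500, {0}, {488}, [t2, t1])
        a, b = annotate_nmd_rules(j, g12, genome), annotate_nmd_rules(j, g21, genome)
        assert (
            a.max_distance_to_last_junction,
            a.median_introns_upstream,
            a.median_introns_downstream,
            a.modal_exon_length,
        ) == (
            b.max_distance_to_last_junction,
            b.median_introns_upstream,
            b.median_introns_downstream,
            b.modal_exon_length,
        )
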