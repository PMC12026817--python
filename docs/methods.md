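# Methods

## Model and procedure

`spliceclass` treats each splice junction as an intron interval
`(chrom, start, end, strand)` over intronic bases, 0-based half-open —
the natural representation of a split read. The question asked of every
junction is combinatorial, not statistical: can it lie on a PTC-free
open reading frame from an annotated start codon to an annotated stop
codon, combining freely with the other observed junctions and with the
junctions of annotated protein-coding transcripts?

### Coordinate conventions

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
and BED are converted at the boundary. Codon positions (start/stop) are
stored as the genomic coordinate of the codon's first base *in
transcription order* — on the minus strand that is the larger genomic
coordinate of the codon. Per gene, the classifier works in a
transcription-oriented frame (offset increases with transcription and
the sequence is reverse-complemented on minus-strand genes), so the
search itself has a single code path for both strands; the
strand-mirror tests pin this symmetry.

### The breadth-first search

A path alternates exonic segments and junctions. The search state is
`(last junction, phase)` with phase the number of bases of the current
codon already consumed at the junction's 3' splice site. This pair fully
determines translation state because the partially consumed codon's
bases are always the last `phase` exonic bases before that junction's
donor — a property the implementation exploits directly when scanning
segments for in-frame stops (stop codons split across a junction are
therefore detected, and a split stop can never match a contiguous
annotated stop codon).

Per state, the search (i) tests whether translation from the 3' splice
site reaches an annotated stop in frame with no earlier stop (the state
"completes"); (ii) attempts extension with every junction whose donor
lies at or downstream of the current position within `max_exon_length`,
discarding extensions whose intervening segment contains an in-frame
stop. Extension is attempted regardless of completion, so alternative
last exons are explored. Revisited states merge their accumulated
junction sets and are not re-expanded. After the queue drains, a reverse
reachability pass over the state graph marks every state from which a
completed state is reachable; the union of their accumulated junction
sets is the productive set. Junctions never marked productive are
unproductive. Expansions are bounded by `3 × (n_junctions + 1)` plus one
per start codon.

Genes lacking a start or a stop codon are non-classifiable and only
contribute annotation bits; genes with more than
`max_junctions_per_gene` (default 1000) merged junctions are skipped
with a warning.

### Flags and categories

Four bits per junction — bit0 UTR, bit1 algorithm-productive, bit2
annotated, bit3 productive-annotated (bit3 ⇒ bit2 is enforced) — are
packed into a decimal flag. The category mapping is exposed as named
constants: flags {0, 1, 4, 5} are the unproductive set and {1, 4} the
UTR-ambiguous set used when filtering; operationally a junction is UTR
when bit0 is set, when its flag is 4 (annotated with no productive
evidence either way), or when it overlaps no classifiable gene;
otherwise productive when bit1 or bit3 is set; otherwise unproductive.
With several overlapping classifiable genes, bit1 is an OR (a junction
productive in any gene context is productive) while bit0 requires the
junction to be outside the START..STOP core of *every* such gene — the
permissive and the conservative choice respectively, matching the
asymmetry of what each bit claims.

### Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `min_cluster_reads` (`-m`) | 30 | minimum pooled reads for a cluster to survive refinement |
| `min_ratio` (`-p`) | 0.001 | minimum within-cluster usage ratio of a junction |
| `max_exon_length` | 5000 nt | cap on a candidate exonic segment between a 3'ss and the next 5'ss |
| `max_junctions_per_gene` | 1000 | search-size cap per gene |
| `min_sample_fraction` | 0.6 | fraction of samples in which a cluster must be observed to become a phenotype |
| `LONG_EXON_THRESHOLD` | 407 nt | modal PTC-exon length at or above which NMD is deemed inefficient |
| `ESCAPE_DISTANCE_NT` | 50 nt | PTC-to-last-junction distance below which NMD is escaped |

`max_exon_length` is a deliberate design choice: unbounded candidate
exons make the search quadratic in gene length and admit biologically
implausible multi-intron read-through "exons"; 5 kb comfortably exceeds
nearly all annotated human internal exons while keeping the search
linear in practice.

### Clustering

Two junctions are connected when they share a donor or an acceptor
coordinate on the same chromosome and strand; such pairs necessarily
overlap, so the overlap requirement of the cluster graph is enforced but
never binds. Refinement removes the lowest-usage member *one at a time*,
re-evaluating ratios after each removal — batch removal would over-prune
because ratios rise as the total shrinks — then re-splits components and
applies the cluster-level read floor to a fixed point. Removed junctions
sharing a splice site with a surviving cluster are re-attached (choosing
the cluster whose sharing member has the highest count; ties go to the
leftmost cluster — the re-attachment rule is a design decision, as is
treating only refinement casualties, not never-clustered singletons, as
candidates). `--include-constitutive` bypasses the two-member minimum so
whole-sample unproductive fractions can be computed over constitutive
junctions too.

### NMD-efficiency rules

Unproductive, non-UTR junctions are substituted into every compatible
protein-coding transcript (compatible = shares donor or acceptor with a
native intron). Substitution moves the exon boundary at the non-matching
end to the query coordinate; exons fully swallowed by the query intron
are only allowed when both query ends sit on native splice sites (an
exon-skipping junction); anything else that would empty or invert an
exon rejects that transcript. For each induced PTC the three metrics are
(a) spliced-nucleotide distance from the PTC to the last exon-exon
junction (max over transcripts; final-exon PTCs are flagged rather than
given a negative distance), (b) introns upstream/downstream of the PTC
(lower median), and (c) PTC-exon length (mode; ties to the smallest).
Distances are spliced-mRNA nucleotides — the quantity the
exon-junction-complex mechanism senses — not genomic. The long-exon
threshold is ≥ 407 nt (the ≥ convention is pinned by a test over the
405–409 series).

### Quantification and phenotypes

PSI is a junction's count over its cluster total per sample, undefined
when the total is zero. Phenotype preparation keeps clusters observed
(total > 0) in ≥ 60% of samples, imputes missing PSI with the junction's
across-sample mean, Z-scores each junction (sample SD; zero-variance
rows become 0 with a warning), and inverse-normal rank-transforms each
sample across junctions (ties get average ranks; rank r of n maps to the
standard-normal quantile of (r − 0.5)/n). The rank axis is switchable to
per-junction. Covariate PC count is chosen by permuting each junction
row independently (seeded) and counting true PCs whose variance exceeds
the permuted matrix's top PC. The per-sample unproductive read fraction
excludes UTR-category reads from numerator and denominator, and its log
(as a percentage) is exported as a confounder covariate.

## What the synthetic data emulates — and what it does not

The generator builds single-gene loci with stop-free canonical reading
frames (codons sampled from the 61 sense codons) and plants the event
classes seen in real data: poison-exon inclusion, frame-shifting and
in-frame exon skipping, and 3'UTR introns. Every intron begins with the
motif `TAACTAACTAA` — a stop codon in all three frames — so read-through
paths are guaranteed to terminate and planted truth labels cannot be
silently broken by a chance stop-free intron; guard bases (C, absent
from every stop codon) protect the canonical frame around planted stops
and skip boundaries. Genes default to a 3-exon, ~600 nt layout with
60 nt UTRs; simulated counts are multinomial draws per cluster at
planted PSI (default unproductive inclusion PSI 0.1, 2000 reads per
cluster, values chosen as a plausible mid-depth bulk RNA-seq regime).

The fixtures do **not** model splice-site sequence motifs, read-level
noise, alignment artifacts, overlapping genes, multi-isoform annotation
complexity, or NMD itself (counts are drawn at the planted PSI, not
depleted post hoc). Passing tests therefore demonstrate the
combinatorial correctness of the classifier and the numerical
correctness of the pipeline on clean inputs — not robustness to
alignment error or annotation noise in real data.

The exhaustive oracle (`brute_force_classify`) enumerates every
coordinate-increasing junction sequence from every start codon and
translates the implied spliced sequence character by character, sharing
no path or translation code with the breadth-first classifier; it caps
enumeration and errors out rather than degrade. Within the oracle, every
accepted path asserts that the spliced CDS length is divisible by 3.

## Numerical and degenerate-input choices

- Zero-length exonic segments (a junction's donor at the current
  position) are permitted in search and oracle alike.
- `first_inframe_stop` scans complete codons only, starting at offset
  `(3 − phase) mod 3`; codons containing N never count as stops.
- Unknown-strand junctions are evaluated against overlapping genes on
  both strands; annotation bits match either strand.
- Deterministic iteration everywhere (coordinate-sorted genes, starts,
  junctions; fixed-mtime gzip), so identical runs are byte-identical.
- Median of intron counts over an even number of transcripts uses the
  lower median, keeping the output integer-valued.
- A transcript whose annotated stop codon is spliced out by a
  substitution treats any in-frame stop found as premature.

## Known limitations

- Start codons are trusted from annotation; no ATG verification, uORF
  detection, or start-codon inference from sequence.
- Selenocysteine recoding (UGA read-through) is not modeled.
- The UTR call uses only the most-downstream START / most-upstream STOP
  of the gene, which can misjudge genes with dramatically different
  isoform-specific CDS extents; with multiple stop codons on different
  transcripts the most upstream STOP is the minimum in transcription
  order over all stop-codon records.
- `build_count_matrix` assigns cells junction-by-junction and targets
  cohort sizes of hundreds of samples, not tens of thousands.
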