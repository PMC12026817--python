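"""Splice-junction records and per-sample junction count I/O.

A junction is an intron excision event observed as a split RNA-seq read:
the intron interval it removes, in 0-based half-open genomic coordinates
over the intronic bases. The donor (5'ss) is the intron boundary nearer
the transcription start, so donor/acceptor assignment flips with strand.
"""

from __future__ import annotations

import gzip
import logging
import os
from typing import Iterable, NamedTuple

log = logging.getLogger(__name__)


class Junction(NamedTuple):
    """An intron interval: ``start`` is the first intronic base, ``end`` one past the last."""

    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' (unknown)

    @property
    def donor(self) -> int:
        """Genomic coordinate of the 5' splice site (strand-aware).

        On '+' (and unknown) strand this is the intron start; on '-' it is
        the intron end. Unknown-strand junctions are resolved against
        overlapping genes at classification time.
        """
        return self.start if self.strand != "-" else self.end

    @property
    def acceptor(self) -> int:
        """Genomic coordinate of the 3' splice site (strand-aware)."""
        return self.end if self.strand != "-" else self.start

    def overlaps(self, other: "Junction") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def name(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"


class SampleJunctionCounts:
    """Junction read counts for one sample."""

    def __init__(self, sample_id: str, counts: dict[Junction, int] | None = None):
        self.sample_id = sample_id
        self.counts: dict[Junction, int] = dict(counts or {})
        for j, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {j.name()} in {sample_id}")

    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_junction_bed(
    path, sample_id: str | None = None, dialect: str = "intron"
) -> SampleJunctionCounts:
    """Read a BED6 splice-junction count file for one sample.

    Columns: chrom, start, end, name, count, strand. Counts live in the
    score column (regtools-style). Two dialects are accepted:

    - ``intron``: start/end already delimit the intron (default);
    - ``anchor``: start/end include read anchor overhangs, with a 12th
      column of two comma-separated block sizes (regtools ``junctions
      extract`` output); overhangs are stripped.

    Duplicate lines for the same junction are summed.
    """
    if dialect not in ("intron", "anchor"):
        raise ValueError(f"unknown BED dialect: {dialect!r}")
    if sample_id is None:
        sample_id = os.path.basename(str(path)).split(".")[0]
    counts: dict[Junction, int] = {}
    n_lines = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
            chrom, start_s, end_s, _name, count_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                count = int(count_s)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate or count") from e
            if dialect == "anchor":
                if len(fields) < 11:
                    raise ValueError(
                        f"{path}:{lineno}: anchor dialect needs BED12 block sizes"
                    )
                block1, block2 = (int(b) for b in fields[10].rstrip(",").split(",")[:2])
                start += block1
                end -= block2
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            if strand not in ("+", "-", "."):
                strand = "."
            j = Junction(chrom, start, end, strand)
            counts[j] = counts.get(j, 0) + count
            n_lines += 1
    if n_lines == 0:
        log.warning("junction file %s is empty", path)
    return SampleJunctionCounts(sample_id, counts)


def write_junction_bed(sample: SampleJunctionCounts, path) -> None:
    """Write counts back out in the ``intron`` BED6 dialect (sorted, deterministic)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for j in sorted(sample.counts):
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.name()}\t{sample.counts[j]}\t{j.strand}\n"
            )


def pool_junctions(samples: Iterable[SampleJunctionCounts]) -> dict[Junction, int]:
    """Sum junction counts over samples (union of junction keys)."""
    samples = list(samples)
    if not samples:
        raise ValueError("pool_junctions requires at least one sample")
    pooled: dict[Junction, int] = {}
    for s in samples:
        for j, c in s.counts.items():
            pooled[j] = pooled.get(j, 0) + c
    return pooled


def write_pooled(pooled: dict[Junction, int], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for j in sorted(pooled):
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t{pooled[j]}\n")


def read_pooled(path) -> dict[Junction, int]:
    pooled: dict[Junction, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            chrom, start, end, strand, count = line.split("\t")
            j = Junction(chrom, int(start), int(end), strand)
            pooled[j] = pooled.get(j, 0) + int(count)
    return pooled
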