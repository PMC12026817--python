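"""Intron clustering: shared-splice-site connected components, usage-based
refinement, and re-introduction of rarely used junctions.

Two junctions are connected when they lie on the same chromosome and
strand, their intron intervals overlap, and they share a donor or an
acceptor coordinate. Connected components are alternative intron
excision events. Refinement iteratively removes the lowest-usage member
(one at a time, re-evaluating ratios after every removal) and re-splits
components; junctions dropped only for low relative usage are then
re-attached to surviving clusters so that depleted unproductive events
are not lost from the output.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

from .junctions import Junction

log = logging.getLogger(__name__)

DEFAULT_MIN_CLUSTER_READS = 30
DEFAULT_MIN_RATIO = 0.001


@dataclass
class IntronCluster:
    cluster_id: str
    junctions: list[Junction]
    counts: dict[Junction, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def chrom(self) -> str:
        return self.junctions[0].chrom

    @property
    def strand(self) -> str:
        return self.junctions[0].strand

    @property
    def span(self) -> tuple[int, int]:
        return min(j.start for j in self.junctions), max(j.end for j in self.junctions)

    def ratios(self) -> dict[Junction, float]:
        t = self.total
        return {j: (c / t if t > 0 else float("nan")) for j, c in self.counts.items()}


@dataclass
class RemovedJunction:
    junction: Junction
    count: int
    reason: str  # 'ratio', 'min_reads', 'cluster_reads', 'singleton'
    source_component: tuple[Junction, ...] = field(default_factory=tuple)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _components(junctions: list[Junction]) -> list[list[Junction]]:
    """Connected components of the shared-donor/shared-acceptor overlap graph,
    computed per (chrom, strand) via union-find over coordinate buckets."""
    uf = _UnionFind(junctions)
    by_start: dict[tuple, list[Junction]] = {}
    by_end: dict[tuple, list[Junction]] = {}
    for j in junctions:
        by_start.setdefault((j.chrom, j.strand, j.start), []).append(j)
        by_end.setdefault((j.chrom, j.strand, j.end), []).append(j)
    for bucket in list(by_start.values()) + list(by_end.values()):
        first = bucket[0]
        for other in bucket[1:]:
            if first.overlaps(other):  # always true for shared-site pairs
                uf.union(first, other)
    comps: dict[Junction, list[Junction]] = {}
    for j in junctions:
        comps.setdefault(uf.find(j), []).append(j)
    return [sorted(c) for c in sorted(comps.values(), key=lambda c: min(c))]


def _name_clusters(components: list[tuple[list[Junction], dict]], single=False):
    out = []
    ordered = sorted(components, key=lambda c: (c[0][0].chrom, min(j.start for j in c[0])))
    for i, (members, counts) in enumerate(ordered, 1):
        cid = f"{members[0].chrom}:clu_{i}_{members[0].strand}"
        out.append(IntronCluster(cid, sorted(members), dict(counts)))
    return out


def build_clusters(
    pooled: dict[Junction, int], include_constitutive: bool = False
) -> tuple[list[IntronCluster], list[RemovedJunction]]:
    """Group pooled junctions into intron clusters (connected components).

    Components of size 1 are set aside as singletons unless
    ``include_constitutive`` is set, in which case every junction is
    emitted (used for whole-sample unproductive-fraction estimates over
    constitutive and rare junctions alike).
    """
    if not pooled:
        raise ValueError("no pooled junctions to cluster")
    comps = _components(sorted(pooled))
    kept, removed = [], []
    for comp in comps:
        if len(comp) >= 2 or include_constitutive:
            kept.append((comp, {j: pooled[j] for j in comp}))
        else:
            removed.append(RemovedJunction(comp[0], pooled[comp[0]], "singleton"))
    return _name_clusters(kept), removed


def refine_clusters(
    clusters: list[IntronCluster],
    min_cluster_reads: int = DEFAULT_MIN_CLUSTER_READS,
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_junction_reads: int = 1,
    include_constitutive: bool = False,
) -> tuple[list[IntronCluster], list[RemovedJunction]]:
    """Iteratively drop rarely used junctions and re-split clusters.

    Within each component the member with the smallest usage ratio is
    removed (if below ``min_ratio`` of the current component total or
    below ``min_junction_reads``), ratios are recomputed, and removal
    repeats until all survivors pass; components are then re-split and
    cluster-level floors applied, to a fixed point.
    """
    removed: list[RemovedJunction] = []
    work = [(list(c.junctions), dict(c.counts)) for c in clusters]
    final = []
    while work:
        members, counts = work.pop(0)
        # one-at-a-time usage filter
        changed = True
        while changed and members:
            changed = False
            total = sum(counts[j] for j in members)
            # lowest ratio first; ties broken by count then coordinate
            worst = min(members, key=lambda j: (counts[j], j))
            if counts[worst] < min_junction_reads or (
                total > 0 and counts[worst] / total < min_ratio
            ):
                reason = "min_reads" if counts[worst] < min_junction_reads else "ratio"
                removed.append(RemovedJunction(worst, counts[worst], reason, tuple(members)))
                members.remove(worst)
                changed = True
        if not members:
            continue
        comps = _components(members)
        if len(comps) > 1:
            work.extend((c, {j: counts[j] for j in c}) for c in comps)
            continue
        total = sum(counts[j] for j in members)
        if total < min_cluster_reads:
            removed.extend(
                RemovedJunction(j, counts[j], "cluster_reads", tuple(members))
                for j in members
            )
            continue
        if len(members) < 2 and not include_constitutive:
            removed.append(RemovedJunction(members[0], counts[members[0]], "singleton"))
            continue
        final.append((members, {j: counts[j] for j in members}))
    return _name_clusters(final), removed


def reintroduce_rare_junctions(
    refined: list[IntronCluster], removed: list[RemovedJunction]
) -> list[IntronCluster]:
    """Re-attach removed junctions that share a splice site with a surviving
    cluster; totals and ratios are recomputed.

    A junction attachable to several clusters joins the one whose
    site-sharing member has the highest pooled count (ties: leftmost
    cluster). Junctions sharing no site with any survivor stay out.
    """
    comps = [(list(c.junctions), dict(c.counts)) for c in refined]
    for rj in sorted(removed, key=lambda r: r.junction):
        j = rj.junction
        best = None  # (neighbor count, cluster index key)
        for idx, (members, counts) in enumerate(comps):
            if j in counts:
                continue
            m = members[0]
            if m.chrom != j.chrom or m.strand != j.strand:
                continue
            sharers = [
                x for x in members if (x.start == j.start or x.end == j.end)
            ]
            if not sharers:
                continue
            ncount = max(counts[x] for x in sharers)
            span_start = min(x.start for x in members)
            key = (-ncount, j.chrom, span_start, idx)
            if best is None or key < best[0]:
                best = (key, idx)
        if best is not None:
            members, counts = comps[best[1]]
            members.append(j)
            members.sort()
            counts[j] = rj.count
    return _name_clusters([(m, c) for m, c in comps])


def cluster_pipeline(
    pooled: dict[Junction, int],
    min_cluster_reads: int = DEFAULT_MIN_CLUSTER_READS,
    min_ratio: float = DEFAULT_MIN_RATIO,
    include_constitutive: bool = False,
) -> list[IntronCluster]:
    """build -> refine -> reintroduce, the default clustering path."""
    built, singletons = build_clusters(pooled, include_constitutive)
    refined, removed = refine_clusters(
        built,
        min_cluster_reads=min_cluster_reads,
        min_ratio=min_ratio,
        include_constitutive=include_constitutive,
    )
    # singletons set aside at build time are not rare-by-ratio; only
    # refinement casualties are candidates for re-attachment
    return reintroduce_rare_junctions(refined, removed)


def write_clusters(clusters: list[IntronCluster], path) -> None:
    """One line per cluster: members as chrom:start:end:clusterID_strand with counts."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for c in clusters:
            short = c.cluster_id.split(":", 1)[1]  # chrom is already the first field
            fields = [
                f"{j.chrom}:{j.start}:{j.end}:{short}:{c.counts[j]}"
                for j in c.junctions
            ]
            fh.write(" ".join(fields) + "\n")


def read_clusters(path) -> list[IntronCluster]:
    opener = gzip.open if str(path).endswith(".gz") else open
    clusters = []
    with opener(path, "rt") as fh:
        for line in fh:
            members, counts = [], {}
            cid = None
            for tok in line.split():
                chrom, start, end, short, count = tok.rsplit(":", 4)
                cid = f"{chrom}:{short}"
                strand = short.rsplit("_", 1)[1]
                j = Junction(chrom, int(start), int(end), strand)
                members.append(j)
                counts[j] = int(count)
            clusters.append(IntronCluster(cid, sorted(members), counts))
    return clusters
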