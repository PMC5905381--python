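"""De novo consensus: overlap detection, single-linkage clustering and
center-star majority consensus of a demultiplexed amplicon read set.

Whole-genome assemblers are awkward at amplicon scale (minimum genome
sizes, consensi the size of single reads), so this stage replaces one with
the amplicon-scale answer: cluster reads on pairwise overlaps, orient each
cluster against its longest read, and call a column-majority consensus
from the induced multiple alignment.  The draft is then refined by the
polish module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from skbio.alignment import pair_align

from ._align import align_to_ref, revcomp
from ._pileup import Pileup
from .seqio import Read

logger = logging.getLogger(__name__)


@dataclass
class AssemblyParams:
    min_read_len: int = 200
    min_overlap: int = 50
    min_overlap_identity: float = 0.7
    max_cluster_divergence: float = 0.15

    def __post_init__(self) -> None:
        if self.min_overlap > self.min_read_len:
            raise ValueError("min_overlap must be <= min_read_len")
        for frac in (self.min_overlap_identity, self.max_cluster_divergence):
            if not 0 < frac <= 1:
                raise ValueError("fractions must be in (0, 1]")


@dataclass
class Contig:
    """A draft or polished consensus sequence."""

    seq: str
    support: int
    cluster_read_ids: frozenset[str] = field(default_factory=frozenset)
    locus_label: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("contig sequence must be nonempty")
        if self.cluster_read_ids and len(self.cluster_read_ids) != self.support:
            raise ValueError("support must equal |cluster_read_ids|")


@dataclass(frozen=True)
class Overlap:
    length: int
    identity: float
    orientation: str  # '+' if b overlaps a as given, '-' if via revcomp(b)


def _overlap_one(a: str, b: str) -> tuple[float, int, float]:
    """Optimal overlap (free-end-gap) alignment; returns (score, span, identity)."""
    score, paths, _ = pair_align(
        a, b, mode="global", sub_score=(1.0, -1.0), gap_cost=(2.0, 1.0),
        free_ends=True, trim_ends=True, max_paths=1,
    )
    path = paths[0]
    ga, gb = path.to_aligned((a, b))
    cols = len(ga)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return float(score), cols, (matches / cols if cols else 0.0)


def pairwise_overlap(a: Read, b: Read, params: AssemblyParams | None = None) -> Overlap | None:
    """Best overlap between two reads, testing both orientations of ``b``.

    Reported only when the aligned span reaches ``min_overlap`` bases at
    ``min_overlap_identity``; handles dovetail and containment overlaps.
    """
    params = params or AssemblyParams()
    best: tuple[float, int, float, str] | None = None
    for orient, bseq in (("+", b.seq), ("-", revcomp(b.seq))):
        score, span, ident = _overlap_one(a.seq, bseq)
        if best is None or score > best[0]:
            best = (score, span, ident, orient)
    _, span, ident, orient = best
    if span < params.min_overlap or ident < params.min_overlap_identity:
        return None
    return Overlap(length=span, identity=ident, orientation=orient)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


_SCREEN_MARGIN = 0.03  # gray zone below the identity threshold -> exact DP
_N_REPRESENTATIVES = 5  # per-component reads tested against other components


def _screen_overlap(a: str, b: str, params: AssemblyParams) -> bool | None:
    """Cheap edlib containment screen for an overlap edge.

    True/False when the containment alignment is decisive either way,
    None when only the exact overlap DP can tell (rare dovetail cases).
    """
    short, long = (a, b) if len(a) <= len(b) else (b, a)
    aln = align_to_ref(short, long)  # tries both orientations
    best_ident = aln.identity if aln is not None else 0.0
    if best_ident >= params.min_overlap_identity and min(len(a), len(b)) >= params.min_overlap:
        return True
    if best_ident < params.min_overlap_identity - _SCREEN_MARGIN:
        return False
    return None


def cluster_reads(reads: list[Read], params: AssemblyParams | None = None) -> list[list[str]]:
    """Single-linkage clustering over the overlap graph.

    Pairs already in the same component are skipped (this cannot change
    the single-linkage result), and once components grow, cross-component
    edges are only probed between each component's first few reads — the
    standard amplicon-clustering concession, exact for clusters up to that
    size.  Clusters are returned as read-id lists, largest first.
    """
    params = params or AssemblyParams()
    eligible = [r for r in reads if len(r) >= params.min_read_len]
    uf = _UnionFind(len(eligible))
    reps: dict[int, list[int]] = {i: [i] for i in range(len(eligible))}
    for i in range(len(eligible)):
        for j in range(i + 1, len(eligible)):
            ri, rj = uf.find(i), uf.find(j)
            if ri == rj:
                continue
            if i not in reps[ri] and j not in reps[rj]:
                continue
            screen = _screen_overlap(eligible[i].seq, eligible[j].seq, params)
            if screen is False:
                continue
            if screen or pairwise_overlap(eligible[i], eligible[j], params) is not None:
                uf.union(i, j)
                root = uf.find(i)
                merged = sorted(set(reps.pop(ri) + reps.pop(rj)))
                reps[root] = merged[:_N_REPRESENTATIVES]
    groups: dict[int, list[str]] = {}
    for idx, r in enumerate(eligible):
        groups.setdefault(uf.find(idx), []).append(r.id)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def build_consensus(cluster_reads_: list[Read]) -> Contig:
    """Center-star column-majority consensus of one read cluster.

    Every read is oriented to and aligned against the longest read; the
    induced pileup is called by per-column majority (gap-majority columns
    drop out, >50%-supported insertions are emitted).
    """
    if not cluster_reads_:
        raise ValueError("cluster must be nonempty")
    anchor = max(cluster_reads_, key=lambda r: (len(r), r.id))
    pile = Pileup(ref_id=anchor.id, length=len(anchor))
    used: list[str] = []
    for read in cluster_reads_:
        aln = align_to_ref(read.seq, anchor.seq, min_identity=0.5)
        if aln is None:
            logger.debug("read %s does not align to cluster anchor %s", read.id, anchor.id)
            continue
        pile.add_alignment(aln)
        used.append(read.id)
    seq = pile.call(ref_seq=anchor.seq, min_depth=1)
    return Contig(seq=seq, support=len(used), cluster_read_ids=frozenset(used))


def select_best_contig(contigs: list[Contig]) -> Contig:
    """Contig with maximal read support; ties to the longer, then
    lexicographically smaller sequence."""
    if not contigs:
        raise ValueError("no contigs to select from")
    return sorted(contigs, key=lambda c: (-c.support, -len(c.seq), c.seq))[0]


def assemble_multiplexed(
    reads: list[Read],
    params: AssemblyParams | None = None,
    n_loci: int = 1,
) -> list[Contig]:
    """Cluster a (possibly multi-locus) read set and return the top
    ``n_loci`` consensus contigs by support."""
    if not reads:
        raise ValueError("empty read set")
    params = params or AssemblyParams()
    by_id = {r.id: r for r in reads}
    clusters = cluster_reads(reads, params)
    contigs = [build_consensus([by_id[i] for i in ids]) for ids in clusters]
    contigs.sort(key=lambda c: (-c.support, -len(c.seq), c.seq))
    if len(contigs) < n_loci:
        logger.warning("only %d cluster(s) found for n_loci=%d", len(contigs), n_loci)
    return contigs[:n_loci]
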