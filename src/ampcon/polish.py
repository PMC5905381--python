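"""Consensus polishing: remap the reads to the draft and re-call it,
iterated to convergence, with explicit homopolymer run-length voting; plus
primer/barcode trimming of the finished consensus.

Signal-level polishing is out of scope, so the polisher works in base
space: each round aligns every read to the current consensus, rebuilds it
by pileup majority (substitutions, insertions and deletions alike), and
re-calls every homopolymer run of two or more bases from the per-read
run-length mode — the error class noisy long reads systematically get
wrong.  Ties vote for the longer run, compensating the deletion bias that
puts under-called lengths in excess at truth-length runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib

from ._align import align_to_ref, edit_distance, revcomp
from ._pileup import Pileup, adjudicate_run_length
from .consensus import Contig
from .demux import BarcodeSpec
from .seqio import Read, SeqRecord

logger = logging.getLogger(__name__)


@dataclass
class PolishReport:
    rounds: int
    changes_per_round: list[int] = field(default_factory=list)
    refinement_edits: int = 0
    final_mapped: int = 0
    mean_depth: float = 0.0
    total_depth: float = 0.0
    warning: str = ""


def homopolymer_adjudicate(observations: dict[int, int]) -> int:
    """Consensus run length from per-read observations: the mode, with ties
    resolved toward the longer length."""
    return adjudicate_run_length(observations)


_REFINE_SUPPORT = 0.25  # minority evidence worth testing against the objective


def _total_cost(oriented_reads: list[str], seq: str) -> int:
    """Sum of global edit distances of the (oriented) reads to ``seq`` —
    the median-string objective the consensus should locally minimize."""
    return sum(edit_distance(r, seq) for r in oriented_reads)


def _refine_candidates(pile: Pileup, cur: str) -> list[tuple[int, int, str]]:
    """Locally supported single edits as (position, span, replacement).

    Majority voting is blind where read evidence splits across equivalent
    alignment paths (a missing base at a run boundary shows up partly as a
    mismatch column, partly as a junction insertion, each below 50%).
    Every junction insertion or column runner-up carried by more than a
    quarter of the covering reads becomes a candidate edit — except edits
    that change a homopolymer run's length, which belong to the run-length
    vote (the edit-distance objective is degenerate exactly there, so the
    two mechanisms would fight).
    """

    def _in_voted_run(p: int, base: str) -> bool:
        """Is cur[p] (or the position left of junction p) part of a run of
        ``base`` of length >= 2 — i.e. territory the vote adjudicates?"""
        s = e = p
        while s > 0 and cur[s - 1] == base:
            s -= 1
        while e < len(cur) and cur[e] == base:
            e += 1
        return e - s >= 2

    cands: list[tuple[int, int, str]] = []
    for j in range(1, pile.length):
        if pile.span[j] > 0 and pile.ins_reads[j] > _REFINE_SUPPORT * pile.span[j]:
            if 2 * pile.ins_reads[j] <= pile.span[j]:  # else call() emitted it
                seq = min(pile.ins_counts[j].items(), key=lambda kv: (-kv[1], kv[0]))[0]
                if len(set(seq)) == 1 and _in_voted_run(j, seq[0]):
                    continue  # would change a voted run's length
                cands.append((j, 0, seq))
    for p in range(pile.length):
        tally = pile.base_counts[p]
        depth = sum(tally.values())
        if depth == 0 or len(tally) < 2:
            continue
        ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        runner = ranked[1]
        if runner[1] > _REFINE_SUPPORT * depth:
            if runner[0] == "-" and _in_voted_run(p, cur[p]):
                continue  # deleting inside a voted run
            if runner[0] not in ("-", cur[p]):
                left = right = 0
                while p - 1 - left >= 0 and cur[p - 1 - left] == runner[0]:
                    left += 1
                while p + 1 + right < len(cur) and cur[p + 1 + right] == runner[0]:
                    right += 1
                if left >= 2 or right >= 2:
                    continue  # substitution extending an adjacent voted run
            cands.append((p, 1, "" if runner[0] == "-" else runner[0]))
    return sorted(cands)


def _median_refine(cur: str, oriented_reads: list[str], pile: Pileup) -> tuple[str, int]:
    """Greedy descent on the median-string objective over candidate edits."""
    accepted = 0
    cost = _total_cost(oriented_reads, cur)
    offset = 0
    for pos, span, repl in _refine_candidates(pile, cur):
        p = pos + offset
        cand = cur[:p] + repl + cur[p + span :]
        cand_cost = _total_cost(oriented_reads, cand)
        if cand_cost < cost:
            cur, cost = cand, cand_cost
            offset += len(repl) - span
            accepted += 1
    return cur, accepted


def polish_consensus(
    draft: Contig,
    reads: list[Read],
    max_rounds: int = 8,
    hp_min_run: int = 2,
    min_identity: float = 0.6,
) -> tuple[Contig, PolishReport]:
    """Iteratively re-call a draft consensus from its own read pileup.

    Each round realigns every read to the current consensus and rebuilds
    it by pileup majority with homopolymer run-length voting (runs of
    ``hp_min_run`` or more).  When a round's majority call is already at a
    fixed point, the round instead tests minority-supported single edits
    outside run territory against the median-string objective (total
    read-to-consensus edit distance), keeping only edits that lower it —
    this resolves isolated-column cases where equivalent alignments split
    the evidence below 50%.  Accepted refinements re-open the majority
    call on the next round; a round with zero changes of either kind ends
    the iteration.  Reads failing ``min_identity`` against the current
    consensus sit out that round.  Depth is reported two ways:
    ``mean_depth`` is the mean per-column aligned depth, while
    ``total_depth`` counts full read lengths (adapter-only junk inflates
    the total but not the mean — the discrepancy is diagnostic).
    """
    if not draft.seq:
        raise ValueError("empty draft")
    if not reads:
        raise ValueError("no reads to polish with")
    cur = draft.seq
    changes: list[int] = []
    last_pile: Pileup | None = None
    mapped_reads: list[Read] = []

    def build_pile(seq: str) -> Pileup:
        nonlocal mapped_reads
        pile = Pileup(ref_id="consensus", length=len(seq))
        mapped_reads = []
        for read in reads:
            aln = align_to_ref(read.seq, seq, min_identity=min_identity)
            if aln is None:
                continue
            pile.add_alignment(aln)
            mapped_reads.append(read)
        return pile

    # each round: majority/run-length voting; at its fixed point, switch to
    # objective-guarded refinement within the same round.  Refinement edits
    # change the read alignments, so the majority call gets another look on
    # the following round; a round with zero changes of either kind ends
    # the iteration.
    refinement_edits = 0
    for _ in range(max_rounds):
        last_pile = build_pile(cur)
        if not mapped_reads:
            logger.warning("no reads map to the draft; returning it unchanged")
            return draft, PolishReport(rounds=0, warning="no reads mapped")
        new = last_pile.call(ref_seq=cur, min_depth=1, hp_min_run=hp_min_run)
        n_changed = edit_distance(cur, new)
        if n_changed == 0:
            oriented = [a.read_seq for a in last_pile.alignments]
            new, accepted = _median_refine(cur, oriented, last_pile)
            refinement_edits += accepted
            n_changed = edit_distance(cur, new)
        changes.append(n_changed)
        cur = new
        if n_changed == 0:
            break
    depth = last_pile.depth()
    report = PolishReport(
        rounds=len(changes),
        changes_per_round=changes,
        refinement_edits=refinement_edits,
        final_mapped=len(mapped_reads),
        mean_depth=float(depth.mean()) if len(depth) else 0.0,
        total_depth=sum(len(r) for r in mapped_reads) / len(cur),
    )
    polished = Contig(
        seq=cur,
        support=draft.support,
        cluster_read_ids=draft.cluster_read_ids,
        locus_label=draft.locus_label,
    )
    return polished, report


def _find_end(pattern: str, target: str, max_edit_frac: float = 0.2):
    """Best near-exact hit of a primer/adapter pattern in an end window."""
    k = math.floor(max_edit_frac * len(pattern))
    res = edlib.align(pattern, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    return res["locations"][0]


def trim_consensus(
    consensus: Contig,
    primers: tuple[str | SeqRecord, str | SeqRecord],
    barcodes: list[BarcodeSpec] | None = None,
    window: int = 150,
) -> tuple[Contig, bool]:
    """Cut a consensus down to the amplicon insert.

    Locates the forward primer near the 5' end and the reverse-complemented
    reverse primer near the 3' end (<=20% edits, both orientations of the
    consensus tried) and removes everything outside them — residual barcode
    and adapter tails go with the flanks.  The output is oriented so the
    forward primer reads 5'->3'.  Returns ``(contig, trimmed)``; when
    neither primer is found the input is returned unchanged with
    ``trimmed=False``.
    """
    pf = primers[0].seq if isinstance(primers[0], SeqRecord) else primers[0]
    pr = primers[1].seq if isinstance(primers[1], SeqRecord) else primers[1]
    prc = revcomp(pr)
    for oriented in (consensus.seq, revcomp(consensus.seq)):
        w = min(len(oriented), window + len(pf))
        hit_f = _find_end(pf, oriented[:w])
        tail_start = max(0, len(oriented) - (window + len(prc)))
        hit_r = _find_end(prc, oriented[tail_start:])
        if hit_f is None and hit_r is None:
            continue
        start = hit_f[1] + 1 if hit_f else 0
        end = tail_start + hit_r[0] if hit_r else len(oriented)
        if end <= start:
            continue
        trimmed = Contig(
            seq=oriented[start:end],
            support=consensus.support,
            cluster_read_ids=consensus.cluster_read_ids,
            locus_label=consensus.locus_label,
        )
        return trimmed, True
    logger.warning("no primer found at either consensus end; returning untrimmed")
    return consensus, False
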