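"""Reference-coordinate pileup: per-column base/deletion tallies plus
per-junction insertion tallies, and the majority-call consensus over them.

Coordinates are 0-based half-open over the reference.  Junction ``j`` sits
between reference positions ``j-1`` and ``j``; an alignment spans it when
it covers both neighbours.  Column majority requires >50% of the reads
covering the column; exact ties resolve by base precedence A<C<G<T with
deletion last, for determinism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._align import RefAlignment

_TIE_ORDER = {b: i for i, b in enumerate("ACGTN-")}


def majority_call(counter: Counter) -> str:
    """Majority symbol of a column tally; ties break A<C<G<T, gap last."""
    best = max(counter.items(), key=lambda kv: (kv[1], -_TIE_ORDER.get(kv[0], 9)))
    return best[0]


def adjudicate_run_length(observations: Counter | dict[int, int]) -> int:
    """Mode of per-read homopolymer run-length observations; ties go to the
    longer length (nanopore deletion bias systematically under-calls runs)."""
    obs = Counter(observations)
    if not obs:
        raise ValueError("no run-length observations")
    return max(obs.items(), key=lambda kv: (kv[1], kv[0]))[0]


def homopolymer_runs(seq: str, min_run: int = 3) -> list[tuple[int, int, str]]:
    """Maximal single-base runs of length >= min_run as (start, end, base)."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j, seq[i]))
        i = j
    return runs


@dataclass
class Pileup:
    """Tallies of aligned reads against one reference sequence."""

    ref_id: str
    length: int
    base_counts: list[Counter] = field(default_factory=list, repr=False)
    ins_counts: list[Counter] = field(default_factory=list, repr=False)
    ins_reads: np.ndarray = field(default=None, repr=False)
    span: np.ndarray = field(default=None, repr=False)
    alignments: list[RefAlignment] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.base_counts:
            self.base_counts = [Counter() for _ in range(self.length)]
            self.ins_counts = [Counter() for _ in range(self.length + 1)]
            self.ins_reads = np.zeros(self.length + 1, dtype=int)
            self.span = np.zeros(self.length + 1, dtype=int)

    @property
    def n_reads(self) -> int:
        return len(self.alignments)

    def depth(self) -> np.ndarray:
        return np.array([sum(c.values()) for c in self.base_counts])

    def add_alignment(self, aln: RefAlignment) -> None:
        """Tally one read-vs-reference alignment into the pileup."""
        pos, q = aln.ref_start, aln.read_start
        read = aln.read_seq
        for op, n in aln.ops:
            if op in "=XM":
                for k in range(n):
                    self.base_counts[pos + k][read[q + k]] += 1
                pos += n
                q += n
            elif op == "I":
                if aln.ref_start < pos < aln.ref_end:
                    self.ins_counts[pos][read[q : q + n]] += 1
                    self.ins_reads[pos] += 1
                q += n
            elif op == "D":
                for k in range(n):
                    self.base_counts[pos + k]["-"] += 1
                pos += n
        self.span[aln.ref_start + 1 : aln.ref_end] += 1
        self.alignments.append(aln)

    def run_length_observations(
        self, runs: list[tuple[int, int, str]]
    ) -> list[Counter]:
        """Per-read homopolymer length counts for each reference run.

        A read observes a run when its alignment spans it fully; the
        observation is the number of read bases carried across the run's
        columns (a substitution inside the run still occupies a position)
        plus inserted bases at interior junctions, plus run-base characters
        inserted at the two boundary junctions or aligned onto the single
        flanking column at either side — equivalent-cost alignments park an
        extra run base there as a mismatch instead of an insertion.
        """
        n_runs = len(runs)
        obs = [Counter() for _ in runs]
        if not n_runs:
            return obs
        L = self.length
        col2run = np.full(L, -1, dtype=np.int64)
        base_u8 = np.zeros(n_runs, dtype=np.uint8)
        # the single column flanking a run on either side absorbs shifted bases
        flank_left = np.full(L, -1, dtype=np.int64)  # col s-1 -> run
        flank_right = np.full(L, -1, dtype=np.int64)  # col e -> run
        for ri, (s, e, base) in enumerate(runs):
            col2run[s:e] = ri
            base_u8[ri] = ord(base)
            if s > 0:
                flank_left[s - 1] = ri
            if e < L:
                flank_right[e] = ri
        # a column between two runs of the same base must not feed both votes
        both = (flank_left >= 0) & (flank_right >= 0)
        both &= base_u8[np.clip(flank_left, 0, None)] == base_u8[np.clip(flank_right, 0, None)]
        flank_left[both] = -1
        starts = np.array([r[0] for r in runs])
        ends = np.array([r[1] for r in runs])
        for aln in self.alignments:
            counts = np.zeros(n_runs, dtype=np.int64)
            pos, q = aln.ref_start, aln.read_start
            for op, n in aln.ops:
                if op in "=XM":
                    seg = col2run[pos : pos + n]
                    hit = seg >= 0
                    if hit.any():
                        counts += np.bincount(seg[hit], minlength=n_runs)
                    chars = np.frombuffer(
                        aln.read_seq[q : q + n].encode("ascii"), dtype=np.uint8
                    )
                    for flank in (flank_left, flank_right):
                        fl = flank[pos : pos + n]
                        m = (fl >= 0) & (chars == base_u8[np.clip(fl, 0, None)])
                        if m.any():
                            counts += np.bincount(fl[m], minlength=n_runs)
                    pos += n
                    q += n
                elif op == "I":
                    left = col2run[pos - 1] if pos > 0 else -1
                    right = col2run[pos] if pos < L else -1
                    if left >= 0 and left == right:  # interior junction
                        counts[left] += n
                    else:
                        piece = aln.read_seq[q : q + n]
                        if left >= 0:
                            counts[left] += piece.count(chr(base_u8[left]))
                        if right >= 0 and right != left:
                            counts[right] += piece.count(chr(base_u8[right]))
                    q += n
                elif op == "D":
                    pos += n
            spanned = (aln.ref_start <= starts) & (aln.ref_end >= ends)
            for ri in np.nonzero(spanned)[0]:
                obs[ri][int(counts[ri])] += 1
        return obs

    def call(
        self,
        ref_seq: str,
        min_depth: int = 1,
        hp_min_run: int | None = None,
    ) -> str:
        """Majority consensus over the pileup.

        Columns with depth below ``min_depth`` emit the reference base
        (reference fill); insertions are emitted when carried by >50% of
        the reads spanning the junction.  With ``hp_min_run`` set, every
        reference homopolymer run of at least that length is re-called by
        per-read run-length voting (mode, ties to longer).
        """
        if len(ref_seq) != self.length:
            raise ValueError("reference length does not match pileup")
        emits: list[str] = []
        for p in range(self.length):
            tally = self.base_counts[p]
            depth = sum(tally.values())
            if depth < min_depth:
                emits.append(ref_seq[p])
            else:
                call = majority_call(tally)
                emits.append("" if call == "-" else call)
        inserts = [""] * (self.length + 1)
        for j in range(1, self.length):
            if self.span[j] > 0 and 2 * self.ins_reads[j] > self.span[j]:
                inserts[j] = min(
                    self.ins_counts[j].items(), key=lambda kv: (-kv[1], kv[0])
                )[0]
        if hp_min_run is not None:
            runs = homopolymer_runs(ref_seq, hp_min_run)
            observations = self.run_length_observations(runs)
            for (s, e, base), obs in zip(runs, observations):
                if not obs:
                    continue
                # only adjust the length of regions the reads themselves call a
                # pure run; interior substitution evidence stays with the
                # column majority
                majority_region = "".join(emits[s:e]) + "".join(inserts[s + 1 : e])
                if set(majority_region) - {base}:
                    continue
                length = adjudicate_run_length(obs)
                emits[s] = base * length
                for p in range(s + 1, e):
                    emits[p] = ""
                for j in range(s + 1, e):
                    inserts[j] = ""
                for j in (s, e):
                    if inserts[j] and set(inserts[j]) == {base}:
                        inserts[j] = ""
        out: list[str] = []
        for p in range(self.length):
            out.append(inserts[p])
            out.append(emits[p])
        out.append(inserts[self.length])
        return "".join(out)
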