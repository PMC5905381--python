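"""Shared pairwise-alignment primitives built on edlib.

All read-vs-reference alignments in the pipeline go through
:func:`align_to_ref`, which performs a banded semi-global alignment in both
orientations and reports the better one as a list of CIGAR-style operations
in reference coordinates.  edlib's extended CIGAR uses ``=`` (match),
``X`` (mismatch), ``I`` (extra base in the query/read) and ``D`` (extra base
in the reference).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

_COMP = str.maketrans("ACGTNacgtn#", "TGCANtgcan#")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse an (extended) CIGAR string into ``[(op, length), ...]``."""
    return [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]


def cigar_stats(ops: list[tuple[str, int]]) -> tuple[int, int]:
    """Return ``(matches, columns)`` of an extended-CIGAR op list."""
    matches = sum(n for op, n in ops if op == "=")
    columns = sum(n for _, n in ops)
    return matches, columns


@dataclass
class RefAlignment:
    """Semi-global alignment of one read against a reference sequence.

    ``read_seq`` is the read in the orientation that aligned (already
    reverse-complemented for minus-strand hits); ``ops`` cover
    ``read_seq[read_start:read_end]`` against ``ref[ref_start:ref_end]``.
    """

    strand: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    ops: list[tuple[str, int]] = field(repr=False)
    identity: float = 0.0
    read_seq: str = field(default="", repr=False)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


def _semiglobal_one(seq: str, ref: str, k: int = -1) -> RefAlignment | None:
    """One-orientation semi-global alignment with free end-gaps on the read.

    The shorter sequence is aligned as an infix of the longer one, so read
    overhangs (adapters, barcodes) and read truncations are both unpenalized.
    """
    if not ref:
        raise ValueError("empty reference")
    if not seq:
        return None
    if len(seq) <= len(ref):
        res = edlib.align(seq, ref, mode="HW", task="path", k=k)
        if res["editDistance"] < 0 or not res.get("cigar"):
            return None
        loc = res["locations"][0]
        ops = parse_cigar(res["cigar"])
        matches, cols = cigar_stats(ops)
        return RefAlignment(
            strand="+",
            ref_start=loc[0],
            ref_end=loc[1] + 1,
            read_start=0,
            read_end=len(seq),
            ops=ops,
            identity=matches / cols if cols else 0.0,
            read_seq=seq,
        )
    # Read longer than reference: align the reference as an infix of the read
    # and swap I/D so ops stay read-vs-reference.
    res = edlib.align(ref, seq, mode="HW", task="path", k=k)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    loc = res["locations"][0]
    swap = {"I": "D", "D": "I"}
    ops = [(swap.get(op, op), n) for op, n in parse_cigar(res["cigar"])]
    matches, cols = cigar_stats(ops)
    return RefAlignment(
        strand="+",
        ref_start=0,
        ref_end=len(ref),
        read_start=loc[0],
        read_end=loc[1] + 1,
        ops=ops,
        identity=matches / cols if cols else 0.0,
        read_seq=seq,
    )


def align_to_ref(
    read_seq: str, ref: str, min_identity: float = 0.0, k: int = -1
) -> RefAlignment | None:
    """Best-of-both-orientations semi-global alignment of a read to ``ref``.

    Returns ``None`` when neither orientation reaches ``min_identity``.
    """
    best: RefAlignment | None = None
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        aln = _semiglobal_one(seq, ref, k=k)
        if aln is None:
            continue
        aln.strand = strand
        if best is None or aln.identity > best.identity:
            best = aln
    if best is None or best.identity < min_identity:
        return None
    return best


def edit_distance(a: str, b: str) -> int:
    """Global (NW) unit-cost edit distance."""
    if not a and not b:
        return 0
    if not a or not b:
        return len(a) + len(b)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]
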