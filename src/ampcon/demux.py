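"""Demultiplexing, junk-read flagging and the quality/length read filter.

Reads are assigned to sample barcodes by a semi-global (free end-gap) edit
distance search of every barcode and its reverse complement inside the
first and last ``window`` bases of the read — barcodes sit near the read
ends in amplicon libraries.  Reads consisting (almost) entirely of
adapter/barcode sequence, the signature of failed adapter ligation, are
flagged separately so they never feed the consensus stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib

from ._align import align_to_ref, parse_cigar, revcomp
from .seqio import Read, SeqRecord, mean_quality

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BarcodeSpec:
    """One sample barcode: the barcode proper plus optional adapter flank."""

    barcode_id: str
    seq: str
    flank: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) < 8:
            raise ValueError(f"barcode {self.barcode_id}: length must be >= 8")


@dataclass
class BarcodeAssignment:
    """Demultiplexing result for one read."""

    read_id: str
    barcode_id: str = UNASSIGNED
    strand: str = "+"
    edits: int | None = None
    adapter_only: bool = False
    adapter_covered_fraction: float = 0.0

    @property
    def assigned(self) -> bool:
        return self.barcode_id != UNASSIGNED


@dataclass
class FilterParams:
    """Strict-inequality quality/length thresholds (Q > 13, length > 200)."""

    min_mean_q: float = 13.0
    min_length: int = 200

    def __post_init__(self) -> None:
        if self.min_mean_q < 0 or self.min_length < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterStats:
    kept: int = 0
    dropped_q: int = 0
    dropped_len: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.dropped_q + self.dropped_len


def default_max_edits(barcodes: list[BarcodeSpec]) -> int:
    """floor(0.25 × shortest barcode length) — typical nanopore barcode identity."""
    return math.floor(0.25 * min(len(b.seq) for b in barcodes))


def locate_barcode(
    read: Read,
    barcodes: list[BarcodeSpec],
    max_edits: int | None = None,
    window: int = 150,
) -> BarcodeAssignment:
    """Find the best-matching barcode in the read's end windows.

    Candidates are every barcode and its reverse complement against the
    first and last ``window`` bases.  Strand follows the orientation of the
    matching barcode sequence: a forward-orientation hit reports "+", a
    reverse-complement hit reports "−" (in double-ligated libraries both
    ends carry the barcode and the 5' hit wins the tie).  Ties break by
    lower edit distance, then 5'-end hit over 3'-end hit, then barcode id.
    """
    if not barcodes:
        raise ValueError("empty barcode set")
    if max_edits is None:
        max_edits = default_max_edits(barcodes)
    if max_edits >= min(len(b.seq) for b in barcodes):
        raise ValueError("max_edits must be smaller than the shortest barcode")
    window = max(window, max(len(b.seq) for b in barcodes))
    win5 = read.seq[:window]
    win3 = read.seq[-window:]
    # (pattern-orientation, end) -> strand of the read
    combos = [
        ("fwd", "5p", "+"),
        ("fwd", "3p", "+"),
        ("rc", "5p", "-"),
        ("rc", "3p", "-"),
    ]
    best: tuple[int, int, str, str] | None = None  # (edits, end-rank, id, strand)
    for bc in barcodes:
        pats = {"fwd": bc.seq, "rc": revcomp(bc.seq)}
        for orient, end, strand in combos:
            target = win5 if end == "5p" else win3
            res = edlib.align(pats[orient], target, mode="HW", task="distance", k=max_edits)
            d = res["editDistance"]
            if d < 0:
                continue
            key = (d, 0 if end == "5p" else 1, bc.barcode_id, strand)
            if best is None or key[:3] < best[:3]:
                best = key
    if best is None:
        return BarcodeAssignment(read_id=read.id)
    return BarcodeAssignment(
        read_id=read.id, barcode_id=best[2], strand=best[3], edits=best[0]
    )


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(iv):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def classify_adapter_only(
    read: Read,
    barcodes: list[BarcodeSpec],
    min_fraction: float = 0.8,
) -> tuple[bool, float]:
    """Flag reads that are (almost) nothing but adapter/barcode sequence.

    Near-exact hits (<=10% edits) of every barcode+flank pattern, in both
    orientations, are located iteratively (masking each hit) and their
    interval union measured against the read length.
    """
    if not read.seq:
        return False, 0.0
    masked = list(read.seq)
    intervals: list[tuple[int, int]] = []
    patterns: list[str] = []
    for bc in barcodes:
        pat = bc.flank + bc.seq
        patterns.extend([pat, revcomp(pat)])
    for pat in patterns:
        k = math.floor(0.10 * len(pat))
        for _ in range(32):  # cap runaway repeats
            res = edlib.align(pat, "".join(masked), mode="HW", task="locations", k=k)
            if res["editDistance"] < 0:
                break
            s, e = res["locations"][0]
            e += 1
            intervals.append((s, e))
            for i in range(s, e):
                masked[i] = "#"
    covered = sum(e - s for s, e in _merge_intervals(intervals))
    fraction = covered / len(read.seq)
    return fraction > min_fraction, fraction


def filter_reads(
    reads: list[Read], params: FilterParams | None = None
) -> tuple[list[Read], FilterStats]:
    """Keep reads with mean quality > min_mean_q AND length > min_length.

    Length is checked first, so a read failing both counts as dropped_len.
    Order is preserved; kept + dropped counts always sum to the input count.
    """
    params = params or FilterParams()
    kept: list[Read] = []
    stats = FilterStats()
    for r in reads:
        if len(r) <= params.min_length:
            stats.dropped_len += 1
        elif mean_quality(r) <= params.min_mean_q:
            stats.dropped_q += 1
        else:
            kept.append(r)
            stats.kept += 1
    return kept, stats


def rescue_unassigned(
    unassigned: list[Read],
    consensi: list[SeqRecord],
    min_identity: float = 0.75,
) -> dict[str, int]:
    """Map barcode-less reads back to the run's consensi and count rescues.

    A read is rescued for its best-matching consensus when the semi-global
    alignment reaches ``min_identity`` over at least half the read length.
    Returns per-consensus counts plus a ``"rescued"`` total.
    """
    if not consensi:
        raise ValueError("consensi must be nonempty")
    counts: dict[str, int] = {c.id: 0 for c in consensi}
    rescued = 0
    for read in unassigned:
        best_id: str | None = None
        best_ident = 0.0
        for c in consensi:
            aln = align_to_ref(read.seq, c.seq)
            if aln is None:
                continue
            span = aln.read_end - aln.read_start
            if span < 0.5 * len(read) or aln.identity < min_identity:
                continue
            if aln.identity > best_ident:
                best_ident = aln.identity
                best_id = c.id
        if best_id is not None:
            counts[best_id] += 1
            rescued += 1
    counts["rescued"] = rescued
    return counts


def demultiplex(
    reads: list[Read],
    barcodes: list[BarcodeSpec],
    max_edits: int | None = None,
    window: int = 150,
    adapter_min_fraction: float = 0.8,
) -> tuple[dict[str, list[Read]], list[BarcodeAssignment]]:
    """Assign every read; adapter-only reads are excluded from barcode bins.

    Returns ``{barcode_id or 'unassigned': reads}`` plus the full
    per-read assignment table.
    """
    bins: dict[str, list[Read]] = {bc.barcode_id: [] for bc in barcodes}
    bins[UNASSIGNED] = []
    assignments: list[BarcodeAssignment] = []
    for read in reads:
        asn = locate_barcode(read, barcodes, max_edits=max_edits, window=window)
        asn.adapter_only, asn.adapter_covered_fraction = classify_adapter_only(
            read, barcodes, min_fraction=adapter_min_fraction
        )
        assignments.append(asn)
        if asn.adapter_only:
            continue  # junk: never feeds consensus building
        bins[asn.barcode_id if asn.assigned else UNASSIGNED].append(read)
    return bins, assignments
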