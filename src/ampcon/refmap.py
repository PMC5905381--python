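"""Reference-guided consensus: map reads to a (possibly heterospecific)
reference and call a majority consensus over the pileup.

Zero-depth columns emit the reference base, so a consensus built against a
divergent congener inherits reference content wherever reads are missing —
the reference bias this strategy is known for, made explicit and
measurable here.  Coordinates are 0-based half-open internally; only
human-readable reports use 1-based positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._align import RefAlignment, align_to_ref
from ._pileup import Pileup
from .consensus import Contig
from .seqio import Read, SeqRecord

logger = logging.getLogger(__name__)

MIN_MAP_IDENTITY = 0.6


def semiglobal_align(read: Read, ref: SeqRecord, band: int = 100) -> RefAlignment | None:
    """Banded semi-global alignment of a read against the reference.

    Both orientations are tried; the band is an edit-distance bound that
    doubles automatically when hit, so a pathological read costs no more
    than an unbanded alignment.  Returns ``None`` below 60% identity.
    """
    if not ref.seq:
        raise ValueError("empty reference")
    k = max(band, 1)
    limit = len(read.seq) + len(ref.seq)
    while True:
        aln = align_to_ref(read.seq, ref.seq, k=k)
        if aln is not None:
            break
        if k > limit:
            return None
        k *= 2
    return aln if aln.identity >= MIN_MAP_IDENTITY else None


def pileup_consensus(
    alignments: list[RefAlignment],
    ref: SeqRecord,
    min_depth: int = 1,
) -> Contig:
    """Majority consensus over read alignments against one reference."""
    if not alignments:
        raise ValueError("no alignments to call a consensus from")
    pile = Pileup(ref_id=ref.id, length=len(ref.seq))
    for aln in alignments:
        pile.add_alignment(aln)
    seq = pile.call(ref_seq=ref.seq, min_depth=min_depth)
    return Contig(seq=seq, support=len(alignments), locus_label=ref.id)


def build_pileup(alignments: list[RefAlignment], ref: SeqRecord) -> Pileup:
    """Expose the raw pileup (for TSV dumps and depth statistics)."""
    pile = Pileup(ref_id=ref.id, length=len(ref.seq))
    for aln in alignments:
        pile.add_alignment(aln)
    return pile


@dataclass
class RefmapResult:
    contig: Contig
    ref_id: str
    n_reads: int
    n_mapped: int

    @property
    def fraction_mapped(self) -> float:
        return self.n_mapped / self.n_reads if self.n_reads else 0.0


def refguided_pipeline(
    reads: list[Read],
    ref: SeqRecord,
    band: int = 100,
    min_depth: int = 1,
    polish_rounds: int = 8,
) -> RefmapResult:
    """Map every read to ``ref``, call the pileup majority consensus, then
    hand the draft to the polisher (remap + majority, homopolymer-aware)."""
    from .polish import polish_consensus  # late import: polish builds on this module's callers

    if not reads:
        raise ValueError("no reads")
    alignments = [a for a in (semiglobal_align(r, ref, band=band) for r in reads) if a]
    if len(alignments) < 2:
        raise ValueError(f"only {len(alignments)} read(s) mapped to {ref.id}; need >= 2")
    draft = pileup_consensus(alignments, ref, min_depth=min_depth)
    polished, _report = polish_consensus(draft, reads, max_rounds=polish_rounds)
    return RefmapResult(
        contig=polished, ref_id=ref.id, n_reads=len(reads), n_mapped=len(alignments)
    )
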