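"""Synthetic nanopore-like amplicon run generator with known ground truth.

Emulates the pathologies of real field amplicon runs: indel-dominated
per-base errors with excess deletions inside homopolymer runs, reads in
both orientations, adapter-only junk reads (the failed-ligation artifact),
low-level cross-locus / random contaminants, and positive-control spike-in
reads.  Every read is wrapped in a synthetic adapter-flank + barcode +
tailed-primer construct, mirroring a PCR-barcoded amplicon library, and the
whole run is a pure function of the seed.

The default error model (3% substitution, 3% insertion, 5% deletion with a
2x deletion boost in homopolymer runs >= 3, ~11% total) approximates
R9-era nanopore basecalls; rates are configuration, not claims about any
particular chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import revcomp
from .demux import BarcodeSpec
from .seqio import Read, SeqRecord, write_fasta, write_fastq

_BASES = np.array(list("ACGT"))

# Fixed synthetic library chemistry: one adapter flank shared by all
# barcodes plus per-set barcode/primer sequences drawn once from a frozen
# generator.  These stand in for vendor kit sequences, which are treated as
# user-supplied input in real runs.
_CHEMISTRY_SEED = 20180402


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def default_flank(length: int = 20) -> str:
    rng = np.random.default_rng(_CHEMISTRY_SEED)
    return _random_seq(rng, length)


def default_barcode_set(n: int = 12, length: int = 24) -> list[BarcodeSpec]:
    """Synthetic barcode set (at most 12, mirroring a 12-plex kit)."""
    if not 1 <= n <= 12:
        raise ValueError("barcode sets hold 1..12 barcodes")
    rng = np.random.default_rng(_CHEMISTRY_SEED + 1)
    flank = default_flank()
    return [
        BarcodeSpec(barcode_id=f"BC{i + 1:02d}", seq=_random_seq(rng, length), flank=flank)
        for i in range(n)
    ]


def default_primer_pair(locus_label: str, length: int = 22) -> tuple[str, str]:
    """Deterministic synthetic forward/reverse primers for a locus label."""
    h = sum(ord(c) * 131**i for i, c in enumerate(locus_label)) % (2**31)
    rng = np.random.default_rng([_CHEMISTRY_SEED + 2, h])
    return _random_seq(rng, length), _random_seq(rng, length)


def random_truth(length: int, seed: int | list[int]) -> str:
    """A uniform-random truth amplicon sequence."""
    rng = np.random.default_rng(seed)
    return _random_seq(rng, length)


@dataclass
class ErrorModel:
    """Per-base error rates of the read simulator."""

    sub_rate: float = 0.03
    ins_rate: float = 0.03
    del_rate: float = 0.05
    hp_del_boost: float = 2.0  # deletion multiplier inside homopolymer runs >= 3
    qual_mean: float = 14.0
    qual_sd: float = 3.0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 0.5:
            raise ValueError("combined error rate must stay below 0.5")


@dataclass
class LocusSpec:
    """One amplicon locus in a simulated run."""

    label: str
    truth: SeqRecord
    barcode_id: str
    n_reads: int
    primer_f: str | None = None
    primer_r: str | None = None

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.primer_f is None or self.primer_r is None:
            f, r = default_primer_pair(self.label)
            self.primer_f = self.primer_f or f
            self.primer_r = self.primer_r or r


@dataclass
class RunConfig:
    """Composition of a simulated multiplexed run.

    The junk fractions are fractions of the *total* run, so locus read
    counts stay exactly as configured; category counts are rounded by
    largest remainder and are therefore deterministic.
    """

    loci: list[LocusSpec]
    barcodes: list[BarcodeSpec] = field(default_factory=default_barcode_set)
    adapter_only_fraction: float = 0.0
    contaminant_fraction: float = 0.0
    control_fraction: float = 0.0
    orientation_prob_reverse: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        fr = self.adapter_only_fraction + self.contaminant_fraction + self.control_fraction
        if fr >= 1:
            raise ValueError("junk fractions must sum to < 1")
        labels = [l.label for l in self.loci]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate locus labels")
        ids = {b.barcode_id for b in self.barcodes}
        for l in self.loci:
            if l.barcode_id not in ids:
                raise ValueError(f"locus {l.label}: barcode {l.barcode_id} not in set")


def _hp_mask(seq: str, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs >= min_run."""
    mask = np.zeros(len(seq), dtype=bool)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def mutate(
    seq: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, dict[str, int]]:
    """Apply the error model to a sequence; returns (mutated, op counts)."""
    hp = _hp_mask(seq)
    n = len(seq)
    del_p = np.where(hp, min(model.del_rate * model.hp_del_boost, 0.95), model.del_rate)
    dels = rng.random(n) < del_p
    subs = rng.random(n) < model.sub_rate
    inss = rng.random(n) < model.ins_rate
    sub_choice = rng.integers(1, 4, size=n)  # offset from original base
    ins_choice = rng.integers(0, 4, size=n)
    out: list[str] = []
    counts = {"sub": 0, "ins": 0, "del": 0}
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}
    for i, base in enumerate(seq):
        if dels[i]:
            counts["del"] += 1
        else:
            if subs[i]:
                out.append(_BASES[(base_index[base] + sub_choice[i]) % 4])
                counts["sub"] += 1
            else:
                out.append(base)
        if inss[i]:
            out.append(_BASES[ins_choice[i]])
            counts["ins"] += 1
    return "".join(out), counts


def _qualities(n: int, model: ErrorModel, rng: np.random.Generator) -> list[int]:
    q = rng.normal(model.qual_mean, model.qual_sd, size=n)
    return np.clip(np.rint(q), 2, 40).astype(int).tolist()


def simulate_read(
    truth: SeqRecord,
    model: ErrorModel,
    rng: np.random.Generator,
    read_id: str = "sim",
    reverse_prob: float = 0.5,
    return_ops: bool = False,
):
    """Simulate one read from a truth sequence.

    The truth is walked base by base emitting substitutions, insertions and
    deletions at the model's rates (deletions boosted inside homopolymer
    runs), the result is reverse-complemented with probability
    ``reverse_prob``, and per-base qualities are drawn from
    Normal(qual_mean, qual_sd) clipped to [2, 40].
    """
    if not truth.seq:
        raise ValueError("truth sequence must be nonempty")
    seq, counts = mutate(truth.seq, model, rng)
    strand = "-" if rng.random() < reverse_prob else "+"
    if strand == "-":
        seq = revcomp(seq)
    read = Read(id=read_id, seq=seq, qual=_qualities(len(seq), model, rng))
    if return_ops:
        return read, strand, counts
    return read, strand


def largest_remainder(fractions: list[float], total: int) -> list[int]:
    """Integer category counts summing to round(sum(f)*total) deterministically."""
    raw = [f * total for f in fractions]
    counts = [int(x) for x in raw]
    want = int(round(sum(raw)))
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders:
        if sum(counts) >= want:
            break
        counts[i] += 1
    return counts


@dataclass
class SimulatedRun:
    """In-memory result of :func:`simulate_run`."""

    reads: list[Read]
    table: pd.DataFrame  # read_id, category, locus, barcode, strand
    truths: dict[str, SeqRecord]
    config: RunConfig
    control: SeqRecord


def _template(locus: LocusSpec, bc: BarcodeSpec, insert: str) -> str:
    return (
        bc.flank
        + bc.seq
        + locus.primer_f
        + insert
        + revcomp(locus.primer_r)
        + revcomp(bc.seq)
        + revcomp(bc.flank)
    )


def simulate_run(config: RunConfig, model: ErrorModel | None = None) -> SimulatedRun:
    """Simulate a multiplexed run; fully determined by ``config.seed``."""
    model = model or ErrorModel()
    rng = np.random.default_rng(config.seed)
    bc_by_id = {b.barcode_id: b for b in config.barcodes}
    control = SeqRecord("control", random_truth(700, [_CHEMISTRY_SEED + 3]))
    n_locus = sum(l.n_reads for l in config.loci)
    f_sum = config.adapter_only_fraction + config.contaminant_fraction + config.control_fraction
    total = int(round(n_locus / (1 - f_sum))) if n_locus else 0
    n_adapter, n_contam, n_control = largest_remainder(
        [config.adapter_only_fraction, config.contaminant_fraction, config.control_fraction],
        total,
    )

    rows: list[dict] = []
    raw: list[tuple[str, str, str, str]] = []  # (category, locus, barcode, template)
    for locus in config.loci:
        bc = bc_by_id[locus.barcode_id]
        for _ in range(locus.n_reads):
            raw.append(("locus", locus.label, bc.barcode_id, _template(locus, bc, locus.truth.seq)))
    for _ in range(n_adapter):
        bc = config.barcodes[rng.integers(len(config.barcodes))]
        piece = bc.flank + bc.seq
        k = int(rng.integers(2, 6))
        tmpl = "".join(piece if rng.random() < 0.5 else revcomp(piece) for _ in range(k))
        raw.append(("adapter_only", "", bc.barcode_id, tmpl))
    for i in range(n_contam):
        locus = config.loci[i % len(config.loci)]
        bc = bc_by_id[locus.barcode_id]
        if len(config.loci) > 1 and rng.random() < 0.5:
            other = config.loci[(i + 1) % len(config.loci)]
            insert = other.truth.seq
        else:
            insert = _random_seq(rng, len(locus.truth.seq))
        raw.append(("contaminant", locus.label, bc.barcode_id, _template(locus, bc, insert)))
    for i in range(n_control):
        locus = config.loci[i % len(config.loci)] if config.loci else None
        bc = bc_by_id[locus.barcode_id] if locus else config.barcodes[0]
        tmpl = bc.flank + bc.seq + control.seq + revcomp(bc.seq) + revcomp(bc.flank)
        raw.append(("control", locus.label if locus else "", bc.barcode_id, tmpl))

    order = rng.permutation(len(raw))
    reads: list[Read] = []
    for out_i, raw_i in enumerate(order):
        category, locus_label, barcode_id, tmpl = raw[raw_i]
        rid = f"sim{out_i:06d}"
        seq, _ = mutate(tmpl, model, rng)
        strand = "-" if rng.random() < config.orientation_prob_reverse else "+"
        if strand == "-":
            seq = revcomp(seq)
        reads.append(Read(id=rid, seq=seq, qual=_qualities(len(seq), model, rng)))
        rows.append(
            {"read_id": rid, "category": category, "locus": locus_label,
             "barcode": barcode_id, "strand": strand}
        )
    table = pd.DataFrame(rows, columns=["read_id", "category", "locus", "barcode", "strand"])
    truths = {l.label: l.truth for l in config.loci}
    return SimulatedRun(reads=reads, table=table, truths=truths, config=config, control=control)


def write_run(run: SimulatedRun, outdir: str | Path, gzip_fastq: bool = False) -> dict[str, Path]:
    """Write a simulated run to disk: FASTQ, truth-table TSV, truth FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fq = outdir / ("reads.fastq.gz" if gzip_fastq else "reads.fastq")
    write_fastq(run.reads, fq)
    tsv = outdir / "truth_table.tsv"
    run.table.to_csv(tsv, sep="\t", index=False)
    fa = outdir / "truth.fasta"
    write_fasta(list(run.truths.values()), fa)
    bc = outdir / "barcodes.tsv"
    pd.DataFrame(
        [{"barcode_id": b.barcode_id, "seq": b.seq, "flank": b.flank} for b in run.config.barcodes]
    ).to_csv(bc, sep="\t", index=False)
    return {"fastq": fq, "truth_table": tsv, "truth_fasta": fa, "barcodes": bc}
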