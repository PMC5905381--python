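"""End-to-end workflow: demux → filter → consensus (de novo and/or
reference-guided) → polish → trim → evaluate, with a reconciling run
report.

The per-barcode report mirrors how field runs are narrated: reads in,
junk and filter losses, best-contig support, consensus length, and — when
a truth sequence is available — percent identity.  Read-count columns
always reconcile: ``reads_in == adapter_only + dropped_len + dropped_q +
kept`` per barcode, with unassigned reads counted at run level.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from .consensus import AssemblyParams, Contig, assemble_multiplexed, select_best_contig
from .demux import BarcodeSpec, FilterParams, demultiplex, filter_reads
from .evaluate import SubsampleScheme, best_orientation_report
from .polish import polish_consensus, trim_consensus
from .refmap import refguided_pipeline
from .seqio import Read, SeqRecord, read_fasta, read_fastq, write_fasta, write_fastq

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the run report is not written."""


@dataclass
class PipelineConfig:
    input_fastq: str | Path = ""
    barcode_path: str | Path = ""  # FASTA (id=barcode) or TSV (barcode_id, seq, flank)
    primer_path: str | Path | None = None  # FASTA: <label>_F / <label>_R pairs
    reference_path: str | Path | None = None
    truth_path: str | Path | None = None
    outdir: str | Path = "ampcon_out"
    strategy: str = "denovo"  # denovo | refmap | both
    filter_params: FilterParams = field(default_factory=FilterParams)
    assembly_params: AssemblyParams = field(default_factory=AssemblyParams)
    subsample: SubsampleScheme | None = None
    n_loci: int = 1
    max_edits: int | None = None
    window: int = 150
    polish_rounds: int = 8
    seed: int = 1
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.input_fastq or not Path(self.input_fastq).exists():
            raise PipelineError(f"input FASTQ not found: {self.input_fastq}")
        if not self.barcode_path or not Path(self.barcode_path).exists():
            raise PipelineError(f"barcode file not found: {self.barcode_path}")
        if self.strategy not in {"denovo", "refmap", "both"}:
            raise PipelineError(f"unknown strategy {self.strategy!r}")
        if self.strategy in {"refmap", "both"} and not self.reference_path:
            raise PipelineError("strategy refmap/both requires a reference")
        for p in (self.primer_path, self.reference_path, self.truth_path):
            if p and not Path(p).exists():
                raise PipelineError(f"input not found: {p}")


def load_barcodes(path: str | Path) -> list[BarcodeSpec]:
    """Barcode set from FASTA (id = barcode_id) or TSV (barcode_id, seq, flank)."""
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        df = pd.read_csv(path, sep="\t")
        return [
            BarcodeSpec(str(r.barcode_id), str(r.seq), "" if pd.isna(getattr(r, "flank", "")) else str(getattr(r, "flank", "")))
            for r in df.itertuples()
        ]
    return [BarcodeSpec(r.id, r.seq) for r in read_fasta(path)]


def load_primer_pairs(path: str | Path) -> dict[str, tuple[str, str]]:
    """Primer FASTA with records named ``<label>_F`` and ``<label>_R``."""
    pairs: dict[str, dict[str, str]] = {}
    for rec in read_fasta(path):
        if rec.id.endswith(("_F", "_R")):
            pairs.setdefault(rec.id[:-2], {})[rec.id[-1]] = rec.seq
    return {k: (v["F"], v["R"]) for k, v in pairs.items() if "F" in v and "R" in v}


def denovo_strategy(
    params: AssemblyParams | None = None,
    primers: tuple[str, str] | None = None,
    polish_rounds: int = 8,
    n_loci: int = 1,
) -> Callable[[list[Read]], Contig]:
    """A cluster → consensus → polish → trim pipeline as a single callable
    (the shape the subsampling experiment consumes)."""

    def run(reads: list[Read]) -> Contig:
        contigs = assemble_multiplexed(reads, params, n_loci=max(n_loci, 1))
        best = select_best_contig(contigs)
        by_id = {r.id: r for r in reads}
        cluster = [by_id[i] for i in best.cluster_read_ids]
        polished, _ = polish_consensus(best, cluster or reads, max_rounds=polish_rounds)
        if primers is not None:
            polished, _ = trim_consensus(polished, primers)
        return polished

    return run


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns {report, meta} and writes
    artifacts (per-barcode FASTQ, assignments, consensi, report TSV/JSON)."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str):
        timings[name] = time.time()
        logger.info("stage %s", name)

    stage("read")
    reads = list(read_fastq(config.input_fastq))
    if not reads:
        raise PipelineError("input FASTQ is empty")
    barcodes = load_barcodes(config.barcode_path)
    primer_pairs = load_primer_pairs(config.primer_path) if config.primer_path else {}
    truths = {r.id: r for r in read_fasta(config.truth_path)} if config.truth_path else {}
    references = read_fasta(config.reference_path) if config.reference_path else []

    stage("demux")
    bins, assignments = demultiplex(
        reads, barcodes, max_edits=config.max_edits, window=config.window
    )
    adapter_only_ids = {a.read_id for a in assignments if a.adapter_only}
    asn_by_id = {a.read_id: a for a in assignments}
    pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "barcode_id": a.barcode_id,
                "strand": a.strand,
                "edits": a.edits,
                "adapter_only": a.adapter_only,
                "adapter_covered_fraction": round(a.adapter_covered_fraction, 4),
            }
            for a in assignments
        ]
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)

    stage("consensus")
    rows = []
    contigs_out: list[SeqRecord] = []
    for bc in barcodes:
        bin_reads = bins[bc.barcode_id]
        n_adapter = sum(
            1
            for r in reads
            if asn_by_id[r.id].barcode_id == bc.barcode_id and r.id in adapter_only_ids
        )
        reads_in = len(bin_reads) + n_adapter
        write_fastq(bin_reads, outdir / f"{bc.barcode_id}.fastq")
        kept, stats = filter_reads(bin_reads, config.filter_params)
        row = {
            "barcode_id": bc.barcode_id,
            "reads_in": reads_in,
            "adapter_only": n_adapter,
            "dropped_len": stats.dropped_len,
            "dropped_q": stats.dropped_q,
            "kept": stats.kept,
        }
        truth = truths.get(bc.barcode_id) if truths else None
        if truth is None and len(truths) == 1:
            truth = next(iter(truths.values()))
        if len(kept) >= 2:
            if config.strategy in {"denovo", "both"}:
                try:
                    contigs = assemble_multiplexed(
                        kept, config.assembly_params, n_loci=config.n_loci
                    )
                    best = select_best_contig(contigs)
                    by_id = {r.id: r for r in kept}
                    cluster = [by_id[i] for i in best.cluster_read_ids]
                    polished, polish_rep = polish_consensus(
                        best, cluster, max_rounds=config.polish_rounds
                    )
                    primers = primer_pairs.get(bc.barcode_id) or (
                        next(iter(primer_pairs.values())) if len(primer_pairs) == 1 else None
                    )
                    if primers:
                        polished, _ = trim_consensus(polished, primers)
                    row.update(
                        support=polished.support,
                        consensus_length=len(polished.seq),
                        mapped_for_polish=polish_rep.final_mapped,
                        mean_depth=round(polish_rep.mean_depth, 1),
                    )
                    contigs_out.append(SeqRecord(f"{bc.barcode_id}_denovo", polished.seq))
                    if truth:
                        rep = best_orientation_report(polished.seq, truth)
                        row["identity_denovo"] = rep.rounded()
                except ValueError as exc:
                    logger.warning("denovo failed for %s: %s", bc.barcode_id, exc)
            if config.strategy in {"refmap", "both"} and references:
                ref = references[0]
                try:
                    res = refguided_pipeline(
                        kept, ref, polish_rounds=config.polish_rounds
                    )
                    contigs_out.append(SeqRecord(f"{bc.barcode_id}_refmap", res.contig.seq))
                    row["refmap_mapped_fraction"] = round(res.fraction_mapped, 3)
                    if truth:
                        rep = best_orientation_report(res.contig.seq, truth)
                        row["identity_refmap"] = rep.rounded()
                except ValueError as exc:
                    logger.warning("refmap failed for %s: %s", bc.barcode_id, exc)
            if "identity_denovo" in row and "identity_refmap" in row:
                row["identity_delta"] = round(
                    row["identity_denovo"] - row["identity_refmap"], 3
                )
        rows.append(row)

    stage("write")
    write_fastq(bins["unassigned"], outdir / "unassigned.fastq")
    if contigs_out:
        write_fasta(contigs_out, outdir / "consensi.fasta")
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    meta = {
        "seed": config.seed,
        "strategy": config.strategy,
        "n_reads": len(reads),
        "unassigned": len(bins["unassigned"]),
        "adapter_only": len(adapter_only_ids),
        "stage_seconds": {
            k: round((list(timings.values()) + [time.time()])[i + 1] - t, 3)
            for i, (k, t) in enumerate(timings.items())
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump({"meta": meta, "report": rows}, fh, indent=2, default=str)
    return {"report": report, "meta": meta}
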