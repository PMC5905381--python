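"""Barcode demultiplexing, adapter-only flagging, quality/length filtering
and unassigned-read rescue."""

import numpy as np
import pytest

from ampcon._align import revcomp
from ampcon.demux import (
    UNASSIGNED,
    BarcodeSpec,
    FilterParams,
    classify_adapter_only,
    demultiplex,
    filter_reads,
    locate_barcode,
    rescue_unassigned,
)
from ampcon.seqio import Read, SeqRecord
from ampcon.simulate import (
    ErrorModel,
    LocusSpec,
    RunConfig,
    default_barcode_set,
    random_truth,
    simulate_run,
)
from conftest import make_read
from oracles import brute_semiglobal_edits, interval_union_coverage

BARCODES = default_barcode_set(4)
BC01, BC02 = BARCODES[0], BARCODES[1]
INSERT = random_truth(500, [7, 7])


class TestLocateBarcode:
    def test_exact_prefix(self):
        read = make_read(BC01.seq + INSERT)
        asn = locate_barcode(read, BARCODES, max_edits=3)
        assert (asn.barcode_id, asn.strand, asn.edits) == ("BC01", "+", 0)

    def test_reverse_complement_read(self):
        read = make_read(revcomp(BC02.seq + INSERT))
        asn = locate_barcode(read, BARCODES, max_edits=3)
        assert (asn.barcode_id, asn.strand, asn.edits) == ("BC02", "-", 0)

    def test_two_substitutions_found_with_oracle_distance(self):
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mutated = flip[BC01.seq[0]] + flip[BC01.seq[4]].join(
            [BC01.seq[1:4], BC01.seq[5:]]
        )  # substitutions at positions 0 and 4
        read = make_read(mutated + INSERT)
        asn = locate_barcode(read, BARCODES, max_edits=3)
        assert asn.barcode_id == "BC01"
        assert asn.edits == brute_semiglobal_edits(BC01.seq, read.seq[:150])
        assert asn.edits == 2

    def test_random_read_unassigned(self):
        rng = np.random.default_rng(11)
        read = make_read("".join(rng.choice(list("ACGT"), size=500)))
        asn = locate_barcode(read, BARCODES, max_edits=3)
        assert not asn.assigned
        # oracle: no barcode (either strand) within 3 edits of either window
        for bc in BARCODES:
            for pat in (bc.seq, revcomp(bc.seq)):
                for window in (read.seq[:150], read.seq[-150:]):
                    assert brute_semiglobal_edits(pat, window) > 3

    def test_empty_barcode_set_raises(self):
        with pytest.raises(ValueError):
            locate_barcode(make_read("ACGT" * 50), [], max_edits=3)


class TestClassifyAdapterOnly:
    def test_pure_adapter_concatenation(self):
        piece = BC01.flank + BC01.seq
        read = make_read(piece + revcomp(piece))
        flagged, fraction = classify_adapter_only(read, BARCODES)
        assert flagged and fraction == pytest.approx(1.0)

    def test_genuine_amplicon_with_barcode(self):
        read = make_read(BC01.seq + INSERT[:560])
        flagged, fraction = classify_adapter_only(read, [BarcodeSpec("BC01", BC01.seq)])
        assert not flagged
        assert fraction == pytest.approx(len(BC01.seq) / len(read), abs=0.02)

    def test_half_covered_read_below_threshold(self):
        piece = BC01.flank + BC01.seq  # 44 bp
        read = make_read(piece + INSERT[: len(piece)])
        flagged, fraction = classify_adapter_only(read, [BC01], min_fraction=0.8)
        assert not flagged
        oracle = interval_union_coverage([(0, len(piece))], len(read))
        assert fraction == pytest.approx(oracle, abs=0.05)

    def test_monotone_in_min_fraction(self):
        piece = BC01.flank + BC01.seq
        read = make_read(piece * 3 + INSERT[:30])
        decisions = [
            classify_adapter_only(read, [BC01], min_fraction=f)[0]
            for f in (0.5, 0.7, 0.9, 0.99)
        ]
        # raising the threshold can only flip True -> False
        assert decisions == sorted(decisions, reverse=True)


class TestFilterReads:
    def test_mixed_set(self):
        reads = [
            make_read("A" * 500, "good", q=20),
            make_read("A" * 150, "short", q=20),
            make_read("A" * 500, "lowq", q=10),
        ]
        kept, stats = filter_reads(reads, FilterParams())
        assert [r.id for r in kept] == ["good"]
        assert (stats.kept, stats.dropped_q, stats.dropped_len) == (1, 1, 1)

    def test_exactly_q13_dropped_strict(self):
        read = make_read("A" * 500, q=13)
        kept, stats = filter_reads([read], FilterParams())
        assert kept == [] and stats.dropped_q == 1

    def test_exactly_200bp_dropped_strict(self):
        kept, stats = filter_reads([make_read("A" * 200, q=20)], FilterParams())
        assert kept == [] and stats.dropped_len == 1

    def test_empty_input(self):
        kept, stats = filter_reads([], FilterParams())
        assert kept == [] and stats.total == 0

    def test_idempotent_and_subsequence(self, small_run):
        kept, _ = filter_reads(small_run.reads)
        kept2, stats2 = filter_reads(kept)
        assert [r.id for r in kept2] == [r.id for r in kept]
        assert stats2.dropped_q == stats2.dropped_len == 0
        ids = [r.id for r in small_run.reads]
        positions = [ids.index(r.id) for r in kept]
        assert positions == sorted(positions)


class TestRescueUnassigned:
    def test_simulated_reads_rescued_to_their_consensus(self, truth500):
        cfg = RunConfig(loci=[LocusSpec("locus1", truth500, "BC01", 10)], seed=3)
        model = ErrorModel(sub_rate=0, ins_rate=0, del_rate=0, qual_mean=20)
        reads = simulate_run(cfg, model).reads
        rng = np.random.default_rng(5)
        randoms = [
            Read(f"rand{i}", "".join(rng.choice(list("ACGT"), size=500)), [20] * 500)
            for i in range(5)
        ]
        counts = rescue_unassigned(reads + randoms, [SeqRecord("A", truth500.seq)])
        assert counts["A"] == 10 and counts["rescued"] == 10

    def test_empty_unassigned(self, truth500):
        counts = rescue_unassigned([], [SeqRecord("A", truth500.seq)])
        assert counts == {"A": 0, "rescued": 0}

    def test_read_equal_to_consensus(self, truth500):
        counts = rescue_unassigned(
            [make_read(truth500.seq)], [SeqRecord("A", truth500.seq)], min_identity=0.99
        )
        assert counts["A"] == 1

    def test_empty_consensi_raises(self):
        with pytest.raises(ValueError):
            rescue_unassigned([make_read("ACGT" * 100)], [])


def test_demultiplex_recovers_simulated_labels():
    """At 5% per-base error and max_edits = 25% of barcode length, >95% of
    reads are assigned to their true barcode with zero mis-assignments."""
    truths = {
        "locusA": SeqRecord("locusA", random_truth(450, [21, 1])),
        "locusB": SeqRecord("locusB", random_truth(450, [21, 2])),
    }
    cfg = RunConfig(
        loci=[
            LocusSpec("locusA", truths["locusA"], "BC01", 100),
            LocusSpec("locusB", truths["locusB"], "BC02", 100),
        ],
        seed=21,
    )
    model = ErrorModel(sub_rate=0.02, ins_rate=0.01, del_rate=0.02)  # ~5% total
    run = simulate_run(cfg, model)
    expected = dict(zip(run.table.read_id, run.table.barcode))
    bins, assignments = demultiplex(run.reads, run.config.barcodes, max_edits=6)
    n_correct = 0
    for asn in assignments:
        if asn.assigned:
            assert asn.barcode_id == expected[asn.read_id], "mis-assignment"
            n_correct += 1
    assert n_correct / len(run.reads) > 0.95
    assert not bins[UNASSIGNED] or len(bins[UNASSIGNED]) < 0.05 * len(run.reads)
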