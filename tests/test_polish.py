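"""Iterative pileup polishing, homopolymer run-length voting and primer
trimming."""

import numpy as np
import pytest

from ampcon._align import revcomp
from ampcon.consensus import Contig
from ampcon.polish import homopolymer_adjudicate, polish_consensus, trim_consensus
from ampcon.simulate import (
    ErrorModel,
    LocusSpec,
    RunConfig,
    default_barcode_set,
    default_primer_pair,
    random_truth,
    simulate_run,
)
from ampcon.seqio import SeqRecord
from conftest import ERROR_FREE, make_read


def contig_of(seq: str, support: int = 1) -> Contig:
    return Contig(seq=seq, support=support)


class TestPolishConsensus:
    def test_perfect_draft_unchanged(self, truth500, clean_reads):
        polished, report = polish_consensus(contig_of(truth500.seq), clean_reads[:20])
        # clean reads carry primer/barcode flanks; the insert region stays put
        assert truth500.seq in polished.seq or truth500.seq in revcomp(polished.seq)

    def test_substituted_draft_restored_by_majority(self, truth500):
        rng = np.random.default_rng(51)
        corrupted = list(truth500.seq)
        for i in rng.choice(len(corrupted), size=5, replace=False):
            corrupted[i] = "ACGT"[("ACGT".index(corrupted[i]) + 1) % 4]
        reads = [make_read(truth500.seq, f"r{i}") for i in range(100)]
        polished, report = polish_consensus(contig_of("".join(corrupted)), reads)
        assert polished.seq == truth500.seq
        assert report.changes_per_round[-1] == 0

    def test_homopolymer_restored_at_depth(self):
        """A draft missing one base of a six-cytosine run is repaired by
        run-length voting on simulated reads at default error rates."""
        truth = SeqRecord(
            "t", random_truth(200, [52, 1]) + "CCCCCC" + random_truth(200, [52, 2])
        )
        assert "CCCCCCC" not in truth.seq
        cfg = RunConfig(loci=[LocusSpec("t", truth, "BC01", 100)], seed=52)
        reads = simulate_run(cfg).reads
        draft = truth.seq.replace("CCCCCC", "CCCCC", 1)
        polished, _ = polish_consensus(contig_of(draft), reads)
        assert "CCCCCC" in polished.seq or "CCCCCC" in revcomp(polished.seq)

    def test_no_mapping_reads_returns_draft_with_warning(self, truth500):
        junk = [make_read(random_truth(400, [53, i]), f"j{i}") for i in range(3)]
        polished, report = polish_consensus(contig_of(truth500.seq), junk)
        assert polished.seq == truth500.seq
        assert report.warning and report.rounds == 0

    def test_deep_errorfree_pileup_overrides_corruption(self, truth500):
        rng = np.random.default_rng(54)
        corrupted = list(truth500.seq)
        idx = rng.choice(len(corrupted), size=25, replace=False)  # 5% of sites
        for i in idx:
            corrupted[i] = "ACGT"[("ACGT".index(corrupted[i]) + 2) % 4]
        reads = [make_read(truth500.seq, f"r{i}") for i in range(100)]
        polished, _ = polish_consensus(contig_of("".join(corrupted)), reads)
        assert polished.seq == truth500.seq

    def test_idempotent_on_converged_consensus(self, truth500):
        cfg = RunConfig(loci=[LocusSpec("locus1", truth500, "BC01", 60)], seed=55)
        reads = simulate_run(cfg).reads
        once, _ = polish_consensus(contig_of(reads[0].seq, support=60), reads)
        twice, report = polish_consensus(once, reads)
        assert twice.seq == once.seq
        assert report.changes_per_round == [0]
        assert report.refinement_edits == 0

    def test_terminates_with_fixed_point_on_fixtures(self, truth500):
        for seed in range(1, 6):
            cfg = RunConfig(loci=[LocusSpec("locus1", truth500, "BC01", 100)], seed=seed)
            reads = simulate_run(cfg).reads
            draft = contig_of(max(reads, key=len).seq, support=100)
            _, report = polish_consensus(draft, reads)
            assert report.changes_per_round[-1] == 0
            assert report.final_mapped >= 95

    def test_depth_report_mean_vs_total(self, truth500):
        """Full-length junk inflates total coverage but not mean aligned
        depth, reproducing the diagnostic discrepancy."""
        reads = [make_read(truth500.seq, f"r{i}") for i in range(20)]
        short = [make_read(truth500.seq[:100] + "ACGT" * 75, f"s{i}") for i in range(10)]
        _, report = polish_consensus(contig_of(truth500.seq, 20), reads + short, min_identity=0.2)
        assert report.total_depth > report.mean_depth


class TestHomopolymerAdjudicate:
    def test_mode(self):
        assert homopolymer_adjudicate({6: 70, 5: 30}) == 6

    def test_tie_goes_longer(self):
        assert homopolymer_adjudicate({5: 50, 6: 50}) == 6

    def test_single_observation(self):
        assert homopolymer_adjudicate({4: 1}) == 4

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            homopolymer_adjudicate({})


class TestTrimConsensus:
    PF, PR = default_primer_pair("locusX")
    TAIL = default_barcode_set(1)[0].flank

    def test_full_construct_trimmed_to_insert(self, truth500):
        cons = self.TAIL + self.PF + truth500.seq + revcomp(self.PR) + self.TAIL
        trimmed, ok = trim_consensus(contig_of(cons), (self.PF, self.PR))
        assert ok and trimmed.seq == truth500.seq

    def test_reverse_oriented_consensus_canonicalized(self, truth500):
        cons = revcomp(self.PF + truth500.seq + revcomp(self.PR))
        trimmed, ok = trim_consensus(contig_of(cons), (self.PF, self.PR))
        assert ok and trimmed.seq == truth500.seq

    def test_already_trimmed_returns_unchanged_with_warning(self, truth500):
        trimmed, ok = trim_consensus(contig_of(truth500.seq), (self.PF, self.PR))
        assert not ok and trimmed.seq == truth500.seq

    def test_primer_with_two_errors_still_found(self, truth500):
        pf_err = "TT" + self.PF[2:]
        cons = pf_err + truth500.seq + revcomp(self.PR)
        trimmed, ok = trim_consensus(contig_of(cons), (self.PF, self.PR))
        assert ok and trimmed.seq == truth500.seq
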