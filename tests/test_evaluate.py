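"""Identity scoring against truth, error classification and the
subsampling experiment mechanics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampcon.consensus import Contig
from ampcon.evaluate import (
    SubsampleScheme,
    best_orientation_report,
    classify_errors,
    compare_strategies,
    global_identity,
    subsample_experiment,
)
from ampcon.seqio import Read, SeqRecord
from ampcon.simulate import random_truth
from oracles import gotoh_score

TRUTH = SeqRecord("truth", random_truth(500, [61, 1]))

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _report_score(report):
    """Reconstruct the alignment score implied by a full-span report:
    +1 match, -1 mismatch, affine gap open -2 / extend -1 per event."""
    score = report.matches - report.substitutions
    for d in report.diff_positions:
        if d.type in ("insertion", "deletion"):
            k = max(len(d.truth_bases), len(d.query_bases))
            score += -2 - (k - 1)
    return score


class TestGlobalIdentity:
    def test_identical(self):
        rep = global_identity(TRUTH, TRUTH)
        assert rep.percent_identity == 100.0
        assert rep.matches == 500 and rep.aligned_columns == 500

    def test_single_deletion(self):
        query = SeqRecord("q", TRUTH.seq[:250] + TRUTH.seq[251:])
        rep = global_identity(query, TRUTH)
        assert rep.percent_identity == pytest.approx(100 * 499 / 500)
        assert rep.deletions == 1 and rep.insertions == 0

    def test_four_base_deletion_is_one_event(self):
        query = SeqRecord("q", TRUTH.seq[:250] + TRUTH.seq[254:])
        rep = global_identity(query, TRUTH)
        assert rep.deletions == 4
        events = [d for d in rep.diff_positions if d.type == "deletion"]
        assert len(events) == 1 and len(events[0].truth_bases) == 4

    def test_untrimmed_query_flanks_not_penalized(self):
        query = SeqRecord("q", "ACGTAC" * 5 + TRUTH.seq + "TGCATG" * 5)
        rep = global_identity(query, TRUTH)
        assert rep.percent_identity == 100.0

    def test_missing_truth_end_penalized(self):
        query = SeqRecord("q", TRUTH.seq[:-20])
        rep = global_identity(query, TRUTH)
        assert rep.percent_identity == pytest.approx(100 * 480 / 500)
        assert rep.deletions == 20

    def test_score_agrees_with_gotoh_oracle_on_random_pairs(self):
        rng = np.random.default_rng(62)
        for trial in range(10):
            truth = "".join(rng.choice(list("ACGT"), size=50))
            q = list(truth)
            for _ in range(rng.integers(0, 5)):
                op = rng.integers(3)
                i = rng.integers(1, len(q) - 1)
                if op == 0:
                    q[i] = "ACGT"[rng.integers(4)]
                elif op == 1 and len(q) > 10:
                    del q[i]
                else:
                    q.insert(i, "ACGT"[rng.integers(4)])
            query = "".join(q)
            rep = global_identity(SeqRecord("q", query), SeqRecord("t", truth))
            if not rep.diff_positions or (
                rep.diff_positions[0].column > 1
                and rep.diff_positions[-1].column < len(truth)
            ):
                assert _report_score(rep) == gotoh_score(query, truth)

    @settings(derandomize=True, max_examples=60)
    @given(dna, dna)
    def test_bookkeeping_identity_holds(self, q, t):
        rep = global_identity(SeqRecord("q", q), SeqRecord("t", t))
        assert rep.matches + rep.substitutions + rep.insertions + rep.deletions == rep.aligned_columns
        assert 0 <= rep.percent_identity <= 100

    def test_symmetric_for_full_length_pairs(self):
        a = TRUTH.seq
        b = TRUTH.seq[:200] + "T" + TRUTH.seq[201:300] + TRUTH.seq[301:]
        r1 = global_identity(SeqRecord("a", a), SeqRecord("b", b))
        r2 = global_identity(SeqRecord("b", b), SeqRecord("a", a))
        assert r1.percent_identity == pytest.approx(r2.percent_identity)


class TestClassifyErrors:
    def test_deletion_in_homopolymer_flagged(self):
        truth = SeqRecord("t", random_truth(100, [63, 1]) + "AAAAA" + random_truth(100, [63, 2]))
        i = truth.seq.find("AAAAA")
        query = SeqRecord("q", truth.seq[:i] + truth.seq[i + 1 :])
        rep = classify_errors(global_identity(query, truth), truth)
        dels = [d for d in rep.diff_positions if d.type == "deletion"]
        assert dels and all(d.homopolymer for d in dels)
        assert rep.homopolymer_indels >= 1

    def test_substitution_in_mixed_context_not_flagged(self):
        i = 250
        base = TRUTH.seq[i]
        query = SeqRecord("q", TRUTH.seq[:i] + {"C": "G", "G": "C"}.get(base, "C") + TRUTH.seq[i + 1 :])
        rep = classify_errors(global_identity(query, TRUTH), TRUTH)
        assert rep.substitutions == 1
        assert rep.homopolymer_indels == 0

    def test_perfect_alignment_no_flags(self):
        rep = classify_errors(global_identity(TRUTH, TRUTH), TRUTH)
        assert rep.homopolymer_indels == 0


class TestSubsampleExperiment:
    READS = [Read(f"r{i}", TRUTH.seq, [20] * 500) for i in range(60)]

    @staticmethod
    def echo_pipeline(reads):
        return Contig(seq=TRUTH.seq, support=len(reads))

    def test_full_scheme_row_count(self):
        scheme = SubsampleScheme(sizes=[5, 10, 20, 40], replicates=3, seed=1)
        table = subsample_experiment(self.READS, TRUTH, scheme, self.echo_pipeline)
        assert len(table) == 12
        assert set(table["size"]) == {5, 10, 20, 40}
        assert (table["percent_identity"] == 100.0).all()

    def test_oversized_level_skipped_with_warning(self, caplog):
        scheme = SubsampleScheme(sizes=[10, 1000], replicates=2, seed=1)
        import logging

        with caplog.at_level(logging.WARNING):
            table = subsample_experiment(self.READS, TRUTH, scheme, self.echo_pipeline)
        assert set(table["size"]) == {10}
        assert any("exceeds" in r.message for r in caplog.records)

    def test_same_seed_reproduces_table(self, truth500, small_run, primers):
        from ampcon.pipeline import denovo_strategy

        reads = [r for r in small_run.reads][:80]
        scheme = SubsampleScheme(sizes=[15], replicates=2, seed=7)
        pipe = denovo_strategy(primers=primers)
        t1 = subsample_experiment(reads, truth500, scheme, pipe)
        t2 = subsample_experiment(reads, truth500, scheme, pipe)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_truth_raises(self):
        with pytest.raises(ValueError):
            subsample_experiment(self.READS, SeqRecord("t", ""), SubsampleScheme(), self.echo_pipeline)


class TestCompareStrategies:
    def test_both_perfect_zero_delta(self):
        c = Contig(seq=TRUTH.seq, support=10)
        _, _, delta = compare_strategies(c, c, TRUTH)
        assert delta == 0.0

    def test_one_error_gives_expected_delta(self):
        imperfect = Contig(seq=TRUTH.seq[:100] + TRUTH.seq[101:], support=10)
        perfect = Contig(seq=TRUTH.seq, support=10)
        _, _, delta = compare_strategies(imperfect, perfect, TRUTH)
        assert delta == pytest.approx(-0.2)
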