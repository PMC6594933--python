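"""Class-code geometry, coding-evidence handling and category typing."""

import numpy as np
import pandas as pd
import pytest

from vernalnc.annotation_io import GenomicInterval, TranscriptModel, query_overlaps
from vernalnc.classification import (
    ClassCode,
    ClassificationConfig,
    UnstrandedTranscriptError,
    assign_class_code,
    category_counts,
    classify_transcripts,
    load_coding_evidence,
)


def _tx(tid, *coords, strand="+", seqid="chr1"):
    return TranscriptModel(tid, tuple(
        GenomicInterval(seqid, s, e, strand) for s, e in coords
    ))


class TestAssignClassCode:
    def test_identical_exon_chain_is_match(self, tiny_reference):
        code = assign_class_code(_tx("T", (100, 200), (300, 400)), tiny_reference)
        assert code.code == "match" and code.host_gene_id == "GA"

    def test_contained_in_intron_is_i(self, tiny_reference):
        code = assign_class_code(_tx("T", (210, 290)), tiny_reference)
        assert code.code == "i" and code.host_gene_id == "GA"
        # strand does not block intron containment, but is recorded
        opp = assign_class_code(_tx("T", (210, 290), strand="-"), tiny_reference)
        assert opp.code == "i" and opp.same_strand_host is False

    def test_antisense_overlap_with_oracle_bp(self, tiny_reference):
        # - strand transcript overlapping GA's + strand exon 100-200 by 150 bp
        tx = _tx("T", (51, 250), strand="-")
        code = assign_class_code(tx, tiny_reference)
        assert code.code == "x" and code.host_gene_id == "GA"
        oracle_bp = min(200, 250) - max(100, 51) + 1
        assert code.overlap_bp == oracle_bp == 101
        wide = assign_class_code(_tx("T", (120, 350), strand="-"), tiny_reference)
        assert wide.overlap_bp == (200 - 120 + 1) + (350 - 300 + 1)

    def test_intergenic_is_u(self, tiny_reference):
        code = assign_class_code(_tx("T", (5000, 5400)), tiny_reference)
        assert code.code == "u" and code.host_gene_id == ""

    def test_same_strand_partial_overlap_is_other(self, tiny_reference):
        code = assign_class_code(_tx("T", (150, 250)), tiny_reference)
        assert code.code == "other" and code.host_gene_id == "GA"

    def test_unstranded_transcript_raises(self, tiny_reference):
        with pytest.raises(UnstrandedTranscriptError):
            assign_class_code(_tx("T", (210, 290), strand="."), tiny_reference)

    def test_invariants_on_codes(self):
        with pytest.raises(ValueError):
            ClassCode("u", host_gene_id="G1")
        with pytest.raises(ValueError):
            ClassCode("x")


class TestCodingEvidence:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert load_coding_evidence(p) == {}

    def test_minimum_evalue_retained(self, tmp_path):
        p = tmp_path / "hits.tsv"
        row = "{}\tS{}\t90\t100\t1\t0\t1\t100\t1\t100\t{}\t200\n"
        p.write_text(row.format("Q1", 1, "1e-5") + row.format("Q1", 2, "1e-30"))
        ev = load_coding_evidence(p)
        assert ev["Q1"].best_evalue == pytest.approx(1e-30)
        assert ev["Q1"].best_hit_id == "S2"

    def test_randomized_minima_match_exhaustive_scan(self, tmp_path):
        rng = np.random.default_rng(9)
        rows, truth = [], {}
        for i in range(500):
            q = f"Q{int(rng.integers(0, 60)):03d}"
            ev = 10.0 ** -float(rng.uniform(0, 50))
            rows.append(f"{q}\tS{i}\t90\t100\t1\t0\t1\t100\t1\t100\t{ev:.6e}\t200\n")
            if q not in truth or ev < truth[q]:
                truth[q] = ev
        p = tmp_path / "hits.tsv"
        p.write_text("".join(rows))
        got = load_coding_evidence(p)
        assert {q: e.best_evalue for q, e in got.items()} == pytest.approx(truth)

    def test_non_numeric_evalue_rows_skipped(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "Q1\tS1\t90\t100\t1\t0\t1\t100\t1\t100\tnot_a_number\t200\n"
            "Q1\tS2\t90\t100\t1\t0\t1\t100\t1\t100\t1e-20\t200\n"
        )
        assert load_coding_evidence(p)["Q1"].best_evalue == pytest.approx(1e-20)


class TestClassifyTranscripts:
    def test_intergenic_category_paths(self, tiny_reference):
        from vernalnc.classification import CodingEvidence

        long_u = _tx("TU", (5000, 5499))
        coding = {"TU": CodingEvidence("TU", 1e-12, "SP1")}
        (ct,) = classify_transcripts([long_u], tiny_reference, coding)
        assert ct.category == "putative_mRNA"  # 1e-12 <= 1e-10
        (ct,) = classify_transcripts([long_u], tiny_reference, {})
        assert ct.category == "lincRNA"
        short_u = _tx("TS", (5000, 5100))
        (ct,) = classify_transcripts([short_u], tiny_reference, {})
        assert ct.category == "excluded" and ct.exclusion_reason == "short"

    def test_short_antisense_excluded(self, tiny_reference):
        (ct,) = classify_transcripts([_tx("T", (100, 199), strand="-")], tiny_reference)
        assert ct.category == "excluded" and ct.exclusion_reason == "short"

    def test_evalue_threshold_monotonicity(self, tiny_reference):
        """Tightening the e-value cutoff only moves putative mRNAs to lincRNAs."""
        from vernalnc.classification import CodingEvidence

        rng = np.random.default_rng(2)
        txs = [_tx(f"T{i}", (5000 + 3000 * i, 5400 + 3000 * i)) for i in range(20)]
        coding = {
            t.transcript_id: CodingEvidence(t.transcript_id, 10.0 ** -float(rng.uniform(2, 30)), "S")
            for t in txs
        }
        previous: set[str] | None = None
        for threshold in (1e-25, 1e-15, 1e-5):
            out = classify_transcripts(
                txs, tiny_reference, coding, ClassificationConfig(evalue_threshold=threshold)
            )
            putative = {c.transcript.transcript_id for c in out if c.category == "putative_mRNA"}
            if previous is not None:
                assert previous <= putative  # larger cutoff admits more hits
            previous = putative

    def test_planted_categories_and_hosts_recovered_exactly(self, dataset, classified):
        truth = dataset.truth
        assert len(classified) == len(truth.category)
        for ct in classified:
            tid = ct.transcript.transcript_id
            assert ct.category == truth.category[tid], tid
            if ct.category in ("NAT", "incRNA"):
                assert ct.class_code.host_gene_id == truth.host_gene[tid]

    def test_categories_partition_and_length_rule(self, classified):
        counts = category_counts(classified)
        assert sum(counts.values()) == len(classified)
        for ct in classified:
            if ct.category in ("lincRNA", "NAT", "incRNA"):
                assert ct.transcript.length >= 200

    def test_lincrnas_have_no_gene_span_overlap(self, dataset, classified):
        for ct in classified:
            if ct.category != "lincRNA":
                continue
            assert not query_overlaps(
                dataset.reference, ct.transcript.interval, "any", feature="span"
            )
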