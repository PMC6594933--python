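"""lncRNA-gene pairing geometry, pattern calls and pair summaries."""

import numpy as np
import pandas as pd
import pytest

from vernalnc import synthetic_data as sd
from vernalnc.annotation_io import AnnotationSet, GenomicInterval, TranscriptModel
from vernalnc.classification import ClassCode, ClassifiedTranscript
from vernalnc.expression_de import differential_expression
from vernalnc.pairing import (
    PairingConfig,
    PairingIntegrityError,
    PairRecord,
    attach_expression,
    expression_pattern,
    pair_lncrnas,
    pairs_table,
    pairs_from_table,
    summarize_pairs,
)


def _linc(tid, start, end):
    tx = TranscriptModel(tid, (GenomicInterval("chr1", start, end, "+"),))
    return ClassifiedTranscript(tx, ClassCode("u"), "lincRNA")


def _gene_annotation(*spans):
    txs = [
        TranscriptModel(f"{gid}.t1", (GenomicInterval("chr1", s, e, "+"),), gid)
        for gid, s, e in spans
    ]
    return AnnotationSet.from_transcripts(txs)


class TestPairLncrnas:
    def test_nat_pairs_with_class_code_host(self, tiny_reference):
        tx = TranscriptModel("N1", (GenomicInterval("chr1", 100, 350, "-"),))
        ct = ClassifiedTranscript(tx, ClassCode("x", "GA", 150), "NAT")
        (pair,) = pair_lncrnas([ct], tiny_reference)
        assert pair.relation == "antisense_overlap"
        assert pair.mrna_gene_id == "GA" and pair.distance_bp == 0

    def test_missing_host_gene_raises_integrity_error(self, tiny_reference):
        tx = TranscriptModel("N1", (GenomicInterval("chr1", 100, 350, "-"),))
        ct = ClassifiedTranscript(tx, ClassCode("x", "GONE", 150), "NAT")
        with pytest.raises(PairingIntegrityError):
            pair_lncrnas([ct], tiny_reference)

    def test_nearest_only_picks_the_1500bp_gene(self):
        ann = _gene_annotation(("GN", 1000, 2000), ("GF", 9000, 9500))
        linc = _linc("L1", 3501, 4000)  # 1500 bp downstream of GN, 5 kb to GF
        (pair,) = pair_lncrnas(
            [linc], ann, PairingConfig(neighbor_policy="nearest_only")
        )
        assert (pair.mrna_gene_id, pair.distance_bp) == ("GN", 1500)

    def test_all_within_window_returns_every_neighbor(self):
        ann = _gene_annotation(("GA", 1000, 2000), ("GB", 5500, 6000))
        linc = _linc("L1", 3501, 4000)  # 1500 to GA, 1499 to GB
        pairs = pair_lncrnas([linc], ann)
        assert {(p.mrna_gene_id, p.distance_bp) for p in pairs} == {
            ("GA", 1500), ("GB", 1499)
        }

    def test_proximal_pairs_match_brute_force_gap_scan(self, dataset, classified):
        config = PairingConfig()
        got = {
            (p.lnc_id, p.mrna_gene_id, p.distance_bp)
            for p in pair_lncrnas(classified, dataset.reference, config)
            if p.relation == "proximal"
        }
        expected = set()
        lincs = [c for c in classified if c.category == "lincRNA"]
        for ct in lincs:
            span = ct.transcript.interval
            for gene in dataset.reference.genes.values():
                gap = span.gap_to(gene.interval)
                if gap is not None and gap <= config.linc_window:
                    expected.add((ct.transcript.transcript_id, gene.gene_id, gap))
        assert got == expected
        # the generator's planted proximal distances are all recovered
        assert {
            (lnc, g, d) for lnc, (g, d) in dataset.truth.proximal.items()
        } <= got


class TestPatterns:
    @pytest.mark.parametrize("lnc,mrna,expected", [
        ("up", "up", "coordinate"),
        ("down", "down", "coordinate"),
        ("up", "down", "antagonistic"),
        ("down", "up", "antagonistic"),
        ("up", "ns", "lnc_only"),
        ("ns", "down", "mrna_only"),
        ("ns", "ns", "neither"),
    ])
    def test_pattern_definitions(self, lnc, mrna, expected):
        assert expression_pattern(lnc, mrna) == expected

    def test_attach_expression_populates_and_drops(self):
        de = pd.DataFrame(
            {"log2_ratio": [2.0, -1.5], "direction": ["up", "down"]},
            index=["L1", "G1"],
        )
        pairs = [
            PairRecord("L1", "NAT", "G1", "antisense_overlap", 0),
            PairRecord("L2", "NAT", "G1", "antisense_overlap", 0),  # L2 missing
        ]
        out = attach_expression(pairs, de)
        assert len(out) == 1
        assert out[0].pattern == "antagonistic"
        assert out[0].lnc_log2_ratio == pytest.approx(2.0)

    def test_pattern_cells_partition_pairs(self, dataset, classified, de_table):
        pairs = attach_expression(
            pair_lncrnas(classified, dataset.reference), de_table
        )
        summary = summarize_pairs(pairs)
        assert sum(summary.pattern_counts.values()) == summary.n_pairs == len(pairs)
        assert sum(summary.cell_counts.values()) == len(pairs)


class TestSummaries:
    def test_independent_effects_have_near_zero_correlation(self):
        ratios = sd.simulate_pair_ratios(500, 0.0, rng=31)
        pairs = [
            PairRecord(f"L{i}", "NAT", f"G{i}", "antisense_overlap", 0,
                       r.lnc_log2_ratio, r.mrna_log2_ratio, "up", "up", "coordinate")
            for i, r in enumerate(ratios.itertuples(index=False))
        ]
        summary = summarize_pairs(pairs)
        assert abs(summary.correlations["NAT"]["pearson_r"]) < 0.15

    def test_planted_correlation_recovered(self):
        ratios = sd.simulate_pair_ratios(500, 0.8, rng=32)
        pairs = [
            PairRecord(f"L{i}", "incRNA", f"G{i}", "intron_host", 0,
                       r.lnc_log2_ratio, r.mrna_log2_ratio, "up", "up", "coordinate")
            for i, r in enumerate(ratios.itertuples(index=False))
        ]
        summary = summarize_pairs(pairs)
        assert summary.correlations["incRNA"]["pearson_r"] == pytest.approx(0.8, abs=0.1)
        assert "spearman_r" in summary.correlations["incRNA"]

    def test_joint_de_fraction_matches_product_of_marginals(self):
        """With independent lnc and mRNA effects, P(both called) ~ p_lnc * p_mrna."""
        rng = np.random.default_rng(41)
        n = 600
        lnc_m, lnc_truth = sd.simulate_planted_effects(180, n - 180, effect=4.0, rng=rng)
        mrna_m, mrna_truth = sd.simulate_planted_effects(180, n - 180, effect=4.0, rng=rng)
        lnc_de = differential_expression(lnc_m)
        mrna_de = differential_expression(mrna_m)
        # pair i-th lnc with a random gene so the two sides are independent
        perm = rng.permutation(n)
        lnc_called = (lnc_de["direction"] != "ns").to_numpy()
        mrna_called = (mrna_de["direction"] != "ns").to_numpy()[perm]
        joint = float(np.mean(lnc_called & mrna_called))
        product = float(np.mean(lnc_called)) * float(np.mean(mrna_called))
        se = np.sqrt(product * (1 - product) / n)
        assert abs(joint - product) <= 3 * se + 1e-9

    def test_tables_roundtrip(self):
        pairs = [
            PairRecord("L1", "NAT", "G1", "antisense_overlap", 0, 1.0, -2.0, "up", "down", "antagonistic"),
            PairRecord("L2", "lincRNA", "G2", "proximal", 1500),
        ]
        assert pairs_from_table(pairs_table(pairs)) == pairs
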