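"""Independent brute-force oracles used by several test modules.

These deliberately avoid the package's interval indexes: every comparison
is an exhaustive scan over raw coordinates, so they can adjudicate the
indexed implementations.
"""

from __future__ import annotations

import math

from vernalnc.annotation_io import AnnotationSet, GenomicInterval, introns_of


def brute_force_overlaps(
    annotation: AnnotationSet,
    query: GenomicInterval,
    same_strand: str = "any",
    feature: str = "exon",
) -> set[tuple]:
    """All-pairs scan over every stored feature; returns comparable keys."""
    hits = set()
    for gene in annotation.genes.values():
        if feature == "span":
            candidates = [(gene.gene_id, "", gene.interval)]
        elif feature == "exon":
            candidates = [
                (gene.gene_id, tx.transcript_id, e)
                for tx in gene.transcripts
                for e in tx.exons
            ]
        else:
            candidates = [
                (gene.gene_id, tx.transcript_id, i)
                for tx in gene.transcripts
                for i in introns_of(tx)
            ]
        for gid, tid, iv in candidates:
            if iv.seqid != query.seqid:
                continue
            bp = max(0, min(iv.end, query.end) - max(iv.start, query.start) + 1)
            if bp < 1:
                continue
            if same_strand == "same" and iv.strand != query.strand:
                continue
            if same_strand == "opposite" and (
                iv.strand == query.strand or "." in (iv.strand, query.strand)
            ):
                continue
            hits.add((gid, tid, iv.start, iv.end, iv.strand, bp))
    return hits


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exact summation of binomial-coefficient ratios."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def bh_step_up(p_values: list[float]) -> list[float]:
    """Textbook BH step-up computed without vectorization."""
    m = len(p_values)
    indexed = sorted(enumerate(p_values), key=lambda t: t[1])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx, p = indexed[rank - 1]
        running = min(running, p * m / rank)
        q[idx] = running
    return q
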