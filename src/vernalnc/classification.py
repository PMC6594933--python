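"""Transcript class-code assignment and lncRNA typing.

Assembled transcripts are compared against a reference annotation purely by
interval geometry and given one of five overlap class codes:

* ``match`` — identical ordered exon boundaries to a reference transcript;
* ``x``     — exon-level overlap with a reference exon on the opposite
  strand and no same-strand exonic overlap (the antisense relation);
* ``i``     — the transcript span lies entirely inside one intron of a
  reference transcript (either strand; the strand relation is recorded);
* ``u``     — no coordinate overlap with any reference gene span on either
  strand (strict intergenicity);
* ``other`` — any remaining reference-associated geometry (same-strand
  partial overlap, multi-intron overlap, ...).

Typing then follows the class code, the mature length, and tabular protein
homology evidence: ``x``/``i`` transcripts of at least ``min_lnc_length`` nt
become NATs and incRNAs; ``u`` transcripts with a protein hit at or below
``evalue_threshold`` become putative mRNAs, the rest become lincRNAs
(subject to the length rule); ``match``/``other`` transcripts are counted
as mRNAs. Class codes are recomputed here from geometry rather than parsed
from an assembler's output, so the pipeline is self-contained;
:func:`load_class_codes` is the alternative entry point for precomputed
code tables.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .annotation_io import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    query_overlaps,
)

logger = logging.getLogger(__name__)

CLASS_CODES = ("match", "x", "i", "u", "other")
CATEGORIES = ("mRNA", "putative_mRNA", "lincRNA", "NAT", "incRNA", "excluded")
LNC_CATEGORIES = ("lincRNA", "NAT", "incRNA")


class UnstrandedTranscriptError(ValueError):
    """Antisense status is undefined for a strandless transcript."""


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the classification step.

    min_lnc_length: minimum mature length (nt) for any lncRNA call (200 nt
        is the standard lncRNA definition).
    evalue_threshold: a protein hit with e-value <= this marks an intergenic
        transcript as coding (putative mRNA) rather than lincRNA.
    min_antisense_overlap_bp: minimum opposite-strand exonic overlap for the
        ``x`` (NAT) call.
    """

    min_lnc_length: int = 200
    evalue_threshold: float = 1e-10
    min_antisense_overlap_bp: int = 1

    def __post_init__(self) -> None:
        if self.min_lnc_length < 1:
            raise ValueError("min_lnc_length must be >= 1")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.min_antisense_overlap_bp < 1:
            raise ValueError("min_antisense_overlap_bp must be >= 1")


@dataclass(frozen=True)
class ClassCode:
    code: str
    host_gene_id: str = ""
    overlap_bp: int = 0
    same_strand_host: bool | None = None

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise ValueError(f"unknown class code {self.code!r}")
        if self.code == "u" and self.host_gene_id:
            raise ValueError("code 'u' cannot carry a host gene")
        if self.code in ("match", "x", "i") and not self.host_gene_id:
            raise ValueError(f"code {self.code!r} requires a host gene")


@dataclass(frozen=True)
class CodingEvidence:
    transcript_id: str
    best_evalue: float | None = None
    best_hit_id: str = ""

    def __post_init__(self) -> None:
        if self.best_evalue is not None and self.best_evalue < 0:
            raise ValueError("e-value must be nonnegative")


@dataclass
class ClassifiedTranscript:
    transcript: TranscriptModel
    class_code: ClassCode
    category: str
    exclusion_reason: str = ""


def _merged_length(segments: list[tuple[int, int]]) -> int:
    segments.sort()
    total, cur_s, cur_e = 0, None, None
    for s, e in segments:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def _exonic_overlap_by_gene(
    transcript: TranscriptModel, reference: AnnotationSet, same_strand: str
) -> dict[str, int]:
    """Merged exonic intersection (bp) of the transcript with each gene."""
    segs: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for exon in transcript.exons:
        for feat, _bp in query_overlaps(reference, exon, same_strand, feature="exon"):
            s = max(exon.start, feat.interval.start)
            e = min(exon.end, feat.interval.end)
            segs[feat.gene_id].append((s, e))
    return {g: _merged_length(v) for g, v in segs.items()}


def _best_host(overlaps: Mapping[str, int]) -> tuple[str, int]:
    # largest overlap wins; ties broken by lexicographically smallest gene_id
    return min(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))


def assign_class_code(
    transcript: TranscriptModel,
    reference: AnnotationSet,
    config: ClassificationConfig | None = None,
) -> ClassCode:
    """Assign an overlap class code to one stranded transcript."""
    config = config or ClassificationConfig()
    if transcript.strand == ".":
        raise UnstrandedTranscriptError(
            f"transcript {transcript.transcript_id} is unstranded"
        )
    span = transcript.interval

    # match: identical ordered exon boundaries to some same-strand reference tx
    match_genes = []
    for feat, _bp in query_overlaps(reference, span, "same", feature="span"):
        gene = reference.genes[feat.gene_id]
        for ref_tx in gene.transcripts:
            if ref_tx.exon_boundaries == transcript.exon_boundaries:
                match_genes.append(gene.gene_id)
                break
    if match_genes:
        return ClassCode("match", min(match_genes), transcript.length, True)

    same = _exonic_overlap_by_gene(transcript, reference, "same")
    opposite = _exonic_overlap_by_gene(transcript, reference, "opposite")

    if not same and opposite:
        host, bp = _best_host(opposite)
        if bp >= config.min_antisense_overlap_bp:
            return ClassCode("x", host, bp, False)

    if not same and not opposite:
        containing = [
            feat
            for feat, _bp in query_overlaps(reference, span, "any", feature="intron")
            if feat.interval.contains(span)
        ]
        if containing:
            containing.sort(key=lambda f: (f.gene_id, f.transcript_id))
            host = containing[0]
            same_strand = any(
                f.interval.strand == transcript.strand for f in containing
            )
            return ClassCode("i", host.gene_id, transcript.length, same_strand)
        if not query_overlaps(reference, span, "any", feature="span"):
            return ClassCode("u")

    combined = {g: same.get(g, 0) + opposite.get(g, 0) for g in set(same) | set(opposite)}
    if combined:
        host, bp = _best_host(combined)
        return ClassCode("other", host, bp, host in same)
    span_hits = {f.gene_id: bp for f, bp in query_overlaps(reference, span, "any", feature="span")}
    host, bp = _best_host(span_hits)
    return ClassCode("other", host, bp, None)


BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def load_coding_evidence(path) -> dict[str, CodingEvidence]:
    """Load a 12-column tabular protein-homology hit file (BLAST outfmt 6).

    Per query, the minimum-e-value hit is retained (first occurrence wins
    ties). Rows with a non-numeric e-value are skipped with a logged count.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", names=BLAST6_COLUMNS, dtype=str
        )
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    evalue = pd.to_numeric(df["evalue"], errors="coerce")
    n_bad = int(evalue.isna().sum())
    if n_bad:
        logger.warning("%d hit rows with non-numeric e-value skipped", n_bad)
    df = df.assign(evalue=evalue).dropna(subset=["evalue"])
    out: dict[str, CodingEvidence] = {}
    for qid, group in df.groupby("qseqid", sort=True):
        best = group.loc[group["evalue"].idxmin()]
        out[str(qid)] = CodingEvidence(str(qid), float(best["evalue"]), str(best["sseqid"]))
    return out


def load_class_codes(path) -> dict[str, ClassCode]:
    """Alternative entry point: a precomputed class-code table.

    Expects a TSV with columns transcript_id, class_code, host_gene_id and
    optionally overlap_bp (e.g. exported from an assembler's comparison
    step and mapped onto this package's code vocabulary).
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "host_gene_id": str})
    out = {}
    for row in df.itertuples(index=False):
        host = getattr(row, "host_gene_id", "") or ""
        if isinstance(host, float):  # NaN from empty cell
            host = ""
        out[str(row.transcript_id)] = ClassCode(
            str(row.class_code), host, int(getattr(row, "overlap_bp", 0) or 0)
        )
    return out


def classify_transcripts(
    assembled: Iterable[TranscriptModel],
    reference: AnnotationSet,
    coding: Mapping[str, CodingEvidence] | None = None,
    config: ClassificationConfig | None = None,
) -> list[ClassifiedTranscript]:
    """Type every assembled transcript; the categories partition the input.

    Extra keys in *coding* (hits for transcripts not in *assembled*) are
    ignored. Unstranded transcripts and sub-length lncRNA candidates are
    returned with category ``excluded`` and an explanatory reason.
    """
    coding = coding or {}
    config = config or ClassificationConfig()
    out: list[ClassifiedTranscript] = []
    for tx in sorted(assembled, key=lambda t: (t.seqid, t.interval.start, t.transcript_id)):
        try:
            code = assign_class_code(tx, reference, config)
        except UnstrandedTranscriptError:
            out.append(
                ClassifiedTranscript(tx, ClassCode("other"), "excluded", "unstranded")
            )
            continue
        category, reason = _categorize(tx, code, coding.get(tx.transcript_id), config)
        out.append(ClassifiedTranscript(tx, code, category, reason))
    return out


def _categorize(
    tx: TranscriptModel,
    code: ClassCode,
    evidence: CodingEvidence | None,
    config: ClassificationConfig,
) -> tuple[str, str]:
    long_enough = tx.length >= config.min_lnc_length
    if code.code in ("match", "other"):
        return "mRNA", ""
    if code.code == "x":
        return ("NAT", "") if long_enough else ("excluded", "short")
    if code.code == "i":
        return ("incRNA", "") if long_enough else ("excluded", "short")
    # code == "u": split on protein homology, then the length rule
    has_hit = (
        evidence is not None
        and evidence.best_evalue is not None
        and evidence.best_evalue <= config.evalue_threshold
    )
    if has_hit:
        return "putative_mRNA", ""
    return ("lincRNA", "") if long_enough else ("excluded", "short")


def category_counts(classified: Iterable[ClassifiedTranscript]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for ct in classified:
        counts[ct.category] += 1
    return counts


def classification_table(classified: Iterable[ClassifiedTranscript]) -> pd.DataFrame:
    rows = []
    for ct in classified:
        span = ct.transcript.interval
        rows.append({
            "transcript_id": ct.transcript.transcript_id,
            "seqid": span.seqid,
            "start": span.start,
            "end": span.end,
            "strand": span.strand,
            "length": ct.transcript.length,
            "class_code": ct.class_code.code,
            "host_gene_id": ct.class_code.host_gene_id,
            "overlap_bp": ct.class_code.overlap_bp,
            "category": ct.category,
            "exclusion_reason": ct.exclusion_reason,
        })
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "seqid", "start", "end", "strand", "length",
            "class_code", "host_gene_id", "overlap_bp", "category", "exclusion_reason",
        ],
    )


def load_classification(path, assembled: Iterable[TranscriptModel]) -> list[ClassifiedTranscript]:
    """Rehydrate ClassifiedTranscript records from a classification TSV."""
    by_id = {t.transcript_id: t for t in assembled}
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        tx = by_id.get(row.transcript_id)
        if tx is None:
            raise ValueError(f"classified transcript {row.transcript_id} not in assembled set")
        out.append(
            ClassifiedTranscript(
                tx,
                ClassCode(row.class_code, row.host_gene_id, int(row.overlap_bp or 0)),
                row.category,
                row.exclusion_reason,
            )
        )
    return out
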