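"""Genome-annotation containers, GTF I/O and strand-aware interval queries.

Coordinates are 1-based and fully closed (the GTF convention) everywhere in
this package; conversion to other conventions (e.g. the half-open BED6
export) happens only at explicit output boundaries.

The :class:`AnnotationSet` maintains three per-chromosome interval indexes —
exons, per-transcript introns and gene spans — which are the geometric
substrate for transcript class-code assignment and lncRNA–gene pairing.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

Strandedness = Literal["same", "opposite", "any"]


class AnnotationError(ValueError):
    """A structural problem in an annotation (coordinates, strands, grouping)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 1-based inclusive on both ends."""

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise AnnotationError(
                f"end < start ({self.end} < {self.start}) on {self.seqid}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Length of the coordinate intersection with *other* (0 if disjoint)."""
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Span-to-span gap in bp; 0 for overlapping or abutting intervals.

        Strand-free. Returns ``None`` when the intervals sit on different
        sequences. Abutting intervals (other.start == self.end + 1) have gap 0.
        """
        if self.seqid != other.seqid:
            return None
        if self.overlap_bp(other) > 0:
            return 0
        if self.end < other.start:
            return other.start - self.end - 1
        return self.start - other.end - 1


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript.

    Exons are stored sorted by coordinate and must be non-overlapping and on
    one seqid/strand. ``length`` is the mature (spliced) length: the sum of
    exon lengths. The 200-nt lncRNA length rule downstream operates on this
    quantity.
    """

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        seqids = {e.seqid for e in exons}
        if len(seqids) != 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} spans multiple seqids: {sorted(seqids)}"
            )
        if len({e.strand for e in exons}) != 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} mixes strands across exons"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"({a.start}-{a.end}, {b.start}-{b.end})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def seqid(self) -> str:
        return self.exons[0].seqid

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.seqid, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def exon_boundaries(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)


def introns_of(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Maximal gaps between consecutive exons of one transcript.

    An n-exon transcript yields at most n-1 introns; a zero-length gap
    (abutting exons) yields no intron.
    """
    introns = []
    for a, b in zip(transcript.exons, transcript.exons[1:]):
        if b.start > a.end + 1:
            introns.append(
                GenomicInterval(transcript.seqid, a.end + 1, b.start - 1, transcript.strand)
            )
    return introns


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing a seqid and strand."""

    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        if len({t.seqid for t in self.transcripts}) != 1:
            raise AnnotationError(f"gene {self.gene_id} spans multiple seqids")
        if len({t.strand for t in self.transcripts}) != 1:
            raise AnnotationError(f"gene {self.gene_id} mixes strands")

    @property
    def interval(self) -> GenomicInterval:
        start = min(t.interval.start for t in self.transcripts)
        end = max(t.interval.end for t in self.transcripts)
        return GenomicInterval(self.transcripts[0].seqid, start, end, self.transcripts[0].strand)


@dataclass(frozen=True)
class Feature:
    """A retrievable indexed feature: an exon, an intron, or a gene span."""

    kind: str  # "exon" | "intron" | "span"
    gene_id: str
    transcript_id: str
    interval: GenomicInterval


class AnnotationSet:
    """Genes plus strand-aware interval indexes over exons, introns and spans."""

    def __init__(self, genes: Iterable[GeneModel] | Mapping[str, GeneModel] = ()):
        if isinstance(genes, Mapping):
            genes = genes.values()
        ordered = sorted(genes, key=lambda g: (g.interval.seqid, g.interval.start, g.gene_id))
        self.genes: dict[str, GeneModel] = {}
        for g in ordered:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.parse_errors: list[str] = []
        self.n_missing_transcript_id: int = 0
        self._trees: dict[str, dict[str, IntervalTree]] = {
            "exon": defaultdict(IntervalTree),
            "intron": defaultdict(IntervalTree),
            "span": defaultdict(IntervalTree),
        }
        for gene in self.genes.values():
            span = gene.interval
            self._trees["span"][span.seqid].addi(
                span.start, span.end + 1, Feature("span", gene.gene_id, "", span)
            )
            for tx in gene.transcripts:
                for exon in tx.exons:
                    self._trees["exon"][exon.seqid].addi(
                        exon.start, exon.end + 1,
                        Feature("exon", gene.gene_id, tx.transcript_id, exon),
                    )
                for intron in introns_of(tx):
                    self._trees["intron"][intron.seqid].addi(
                        intron.start, intron.end + 1,
                        Feature("intron", gene.gene_id, tx.transcript_id, intron),
                    )

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "AnnotationSet":
        by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
        for tx in transcripts:
            by_gene[tx.gene_id or tx.transcript_id].append(tx)
        return cls(GeneModel(gid, txs) for gid, txs in by_gene.items())

    def transcripts(self) -> list[TranscriptModel]:
        out = [t for g in self.genes.values() for t in g.transcripts]
        out.sort(key=lambda t: (t.seqid, t.interval.start, t.transcript_id))
        return out

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return {g: m.transcripts for g, m in self.genes.items()} == {
            g: m.transcripts for g, m in other.genes.items()
        }


def _strand_ok(query_strand: str, hit_strand: str, same_strand: Strandedness) -> bool:
    if same_strand == "any":
        return True
    if query_strand == "." or hit_strand == ".":
        raise AnnotationError(
            "strand-restricted query against unstranded interval is undefined"
        )
    return (hit_strand == query_strand) == (same_strand == "same")


def query_overlaps(
    index: AnnotationSet,
    query: GenomicInterval,
    same_strand: Strandedness = "any",
    feature: str = "exon",
) -> list[tuple[Feature, int]]:
    """All indexed features of *feature* kind overlapping *query* by >= 1 bp.

    ``same_strand`` restricts hits to the query's strand ("same"), the
    complementary strand ("opposite"), or no restriction ("any"). Results are
    deterministically ordered by coordinate then ids.
    """
    tree = index._trees[feature].get(query.seqid)
    if tree is None:
        return []
    hits = []
    for iv in tree.overlap(query.start, query.end + 1):
        feat: Feature = iv.data
        if not _strand_ok(query.strand, feat.interval.strand, same_strand):
            continue
        bp = feat.interval.overlap_bp(query)
        if bp >= 1:
            hits.append((feat, bp))
    hits.sort(key=lambda h: (
        h[0].interval.start, h[0].interval.end, h[0].gene_id, h[0].transcript_id, h[0].kind
    ))
    return hits


def read_gtf(path, feature_policy: str = "exon") -> AnnotationSet:
    """Read a GTF2.2 file into an :class:`AnnotationSet`.

    Rows whose feature column equals *feature_policy* (default ``exon``)
    define transcript structure; other rows are ignored. Malformed records
    (unparseable line, end < start, multi-seqid transcript) are skipped and
    reported in ``AnnotationSet.parse_errors`` with their line numbers; rows
    lacking a transcript_id are counted in ``n_missing_transcript_id``.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = defaultdict(list)
    gene_by_tx: dict[str, str] = {}
    errors: list[str] = []
    n_missing = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # record-level: report and continue
                errors.append(f"line {lineno}: unparseable record ({exc})")
                continue
            if feat.featuretype != feature_policy:
                continue
            if feat.end is None or feat.start is None or feat.end < feat.start:
                errors.append(f"line {lineno}: malformed coordinates ({feat.start}-{feat.end})")
                continue
            tid = (feat.attributes.get("transcript_id") or [None])[0]
            if not tid:
                n_missing += 1
                continue
            gid = (feat.attributes.get("gene_id") or [""])[0] or ""
            try:
                exons_by_tx[tid].append(
                    GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand or ".")
                )
            except AnnotationError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            if tid in gene_by_tx and gene_by_tx[tid] != gid:
                errors.append(
                    f"line {lineno}: transcript {tid} maps to conflicting gene_ids"
                )
            gene_by_tx.setdefault(tid, gid)
    transcripts = []
    for tid in sorted(exons_by_tx):
        try:
            transcripts.append(
                TranscriptModel(tid, tuple(exons_by_tx[tid]), gene_by_tx.get(tid, ""))
            )
        except AnnotationError as exc:
            errors.append(f"transcript {tid}: {exc}")
    transcripts.sort(key=lambda t: (t.seqid, t.interval.start, t.transcript_id))
    ann = AnnotationSet.from_transcripts(transcripts)
    ann.parse_errors = errors
    ann.n_missing_transcript_id = n_missing
    if n_missing:
        logger.warning("%d %s rows without transcript_id rejected", n_missing, feature_policy)
    if errors:
        logger.warning("%d malformed GTF records skipped", len(errors))
    return ann


def _gtf_attrs(gene_id: str, transcript_id: str) -> str:
    return f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'


def write_gtf(annotation: AnnotationSet, path) -> None:
    """Write an :class:`AnnotationSet` as GTF2.2; round-trips through read_gtf."""
    with open(path, "w") as fh:
        fh.write("##gtf-version 2.2\n")
        for tx in annotation.transcripts():
            span = tx.interval
            fh.write(
                "\t".join([
                    span.seqid, "vernalnc", "transcript", str(span.start), str(span.end),
                    ".", span.strand, ".", _gtf_attrs(tx.gene_id or tx.transcript_id, tx.transcript_id),
                ]) + "\n"
            )
            for exon in tx.exons:
                fh.write(
                    "\t".join([
                        exon.seqid, "vernalnc", "exon", str(exon.start), str(exon.end),
                        ".", exon.strand, ".", _gtf_attrs(tx.gene_id or tx.transcript_id, tx.transcript_id),
                    ]) + "\n"
                )


def write_bed6(intervals: Iterable[tuple[str, GenomicInterval]], path) -> None:
    # BED is 0-based half-open: convert at this boundary only
    with open(path, "w") as fh:
        for name, iv in intervals:
            fh.write(f"{iv.seqid}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
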