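"""Synthetic annotated genome with planted lncRNAs, effects and pair patterns.

The generator emulates the study design the pipeline targets: a compact
multi-chromosome gene annotation; an "assembled" transcript set containing
reference-matching mRNAs plus planted lincRNAs, NATs, incRNAs, putative
mRNAs and short decoys; a two-condition (NV vs V), two-replicate FPKM
matrix with planted log2 effects and planted NAT/incRNA pair patterns; a
tabular protein-hit file; and a functional-term map with one planted
enriched term. Geometry margins (>= 50 bp antisense exon overlap, >= 10 bp
intron margins, intergenic gaps exceeding twice the lincRNA pairing window)
guarantee unambiguous class codes, so classification recovery can be exact.
Everything is coordinate-level only — no sequences — and fully
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    introns_of,
    write_gtf,
)
from .enrichment import TermMap, write_term_map
from .expression_de import ExpressionMatrix


class SimulationError(ValueError):
    """The requested configuration is geometrically or logically infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Counts mirror a desk-scale version of the study: ~50 protein-coding
    genes and ~100 planted transcripts across every classification path.
    ``intergenic_gap`` must exceed twice ``linc_window`` so that
    non-proximal lincRNAs can be placed unambiguously outside every
    pairing window. Expression is log2-normal: FPKM =
    2^(baseline + effect·[V] + noise), with lncRNA baselines drawn lower
    than mRNA baselines. Pair quotas plant NAT/incRNA pairs whose joint
    pattern (coordinate, antagonistic, one-sided) is guaranteed by shared
    or opposing planted effects of magnitude ``pair_effect_size``.
    """

    seed: int = 42
    n_chromosomes: int = 3
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (200, 400)
    intron_length: tuple[int, int] = (320, 800)
    intergenic_gap: tuple[int, int] = (5000, 7000)
    linc_window: int = 2000

    n_mrna_match: int = 15
    n_nat: int = 25
    n_inc: int = 10
    n_linc: int = 40
    n_linc_proximal: int = 10
    n_putative_mrna: int = 10
    n_short_decoys: int = 2
    min_nat_overlap: int = 50

    n_replicates: int = 2
    mrna_log2_baseline: tuple[float, float] = (5.0, 1.5)  # mean, sd
    lnc_log2_baseline: tuple[float, float] = (2.0, 1.5)
    replicate_noise_sd: float = 0.25
    de_fraction: float = 0.35
    effect_size_grid: tuple[float, ...] = (1.0, 2.0, 4.0)

    pair_effect_size: float = 4.0
    n_pair_coordinate: int = 6
    n_pair_antagonistic: int = 2
    n_pair_lnc_only: int = 2
    n_pair_mrna_only: int = 2
    n_pair_inc_coordinate: int = 2

    n_terms: int = 30
    term_size: tuple[int, int] = (5, 20)
    n_decoy_hits: int = 8


@dataclass
class SyntheticTruth:
    """Planted ground truth, keyed the same way the emitted files are."""

    category: dict[str, str] = field(default_factory=dict)  # assembled id -> category
    host_gene: dict[str, str] = field(default_factory=dict)
    proximal: dict[str, tuple[str, int]] = field(default_factory=dict)  # linc -> (gene, gap)
    effect: dict[str, float] = field(default_factory=dict)  # feature -> planted log2 effect
    pairs: list[tuple[str, str, str]] = field(default_factory=list)  # (lnc, gene, pattern)
    enriched_terms: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class GapSlot:
    """An intergenic interval between (or beside) consecutive genes."""

    seqid: str
    start: int
    end: int
    left_gene: str = ""
    right_gene: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    reference: AnnotationSet
    gaps: list[GapSlot]
    assembled: list[TranscriptModel]
    expression: ExpressionMatrix
    hits: pd.DataFrame
    terms: TermMap
    truth: SyntheticTruth


def _ri(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _validate(config: SimulationConfig) -> None:
    c = config
    if c.intergenic_gap[0] <= 2 * c.linc_window:
        raise SimulationError("intergenic_gap must exceed 2 x linc_window")
    if c.exon_length[0] < 200 and c.n_nat > 0:
        raise SimulationError("exons must be >= 200 bp to host planted NATs")
    if c.intron_length[0] < 220 and c.n_inc > 0:
        raise SimulationError("introns must be >= 220 bp to host planted incRNAs")
    n_quota = (
        c.n_pair_coordinate + c.n_pair_antagonistic + c.n_pair_lnc_only + c.n_pair_mrna_only
    )
    if n_quota > c.n_nat:
        raise SimulationError("pair quotas exceed the number of planted NATs")
    if c.n_pair_inc_coordinate > c.n_inc:
        raise SimulationError("incRNA pair quota exceeds the number of planted incRNAs")
    if c.n_linc_proximal > c.n_linc:
        raise SimulationError("n_linc_proximal exceeds n_linc")
    if c.n_nat + 1 > c.n_genes and c.n_short_decoys > 1:
        raise SimulationError("not enough genes for NAT hosts plus the antisense decoy")


def generate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[AnnotationSet, list[GapSlot]]:
    """Non-overlapping multi-exon genes on ``n_chromosomes`` chromosomes.

    Returns the annotation plus the list of intergenic gap slots used later
    to place intergenic transcripts. Deterministic under the config seed.
    """
    _validate(config)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gaps: list[GapSlot] = []
    gene_no = 0
    for ci, n_here in enumerate(per_chrom, start=1):
        seqid = f"chr{ci}"
        gap_start = 1
        pos = 1 + _ri(rng, *config.intergenic_gap)
        prev_gene = ""
        for _ in range(n_here):
            gene_no += 1
            gid = f"G{gene_no:04d}"
            gaps.append(GapSlot(seqid, gap_start, pos - 1, prev_gene, gid))
            k = _ri(rng, *config.exons_per_gene)
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cursor = pos
            for ei in range(k):
                elen = _ri(rng, *config.exon_length)
                exons.append(GenomicInterval(seqid, cursor, cursor + elen - 1, strand))
                cursor += elen
                if ei < k - 1:
                    cursor += _ri(rng, *config.intron_length)
            genes.append(GeneModel(gid, [TranscriptModel(f"{gid}.t1", tuple(exons), gid)]))
            gap_start = exons[-1].end + 1
            pos = exons[-1].end + 1 + _ri(rng, *config.intergenic_gap)
            prev_gene = gid
        gaps.append(GapSlot(seqid, gap_start, pos - 1, prev_gene, ""))
    return AnnotationSet(genes), gaps


def _place_intergenic(
    slot: GapSlot,
    span_len: int,
    window: int,
    rng: np.random.Generator,
    left_gap: int | None = None,
) -> int:
    """Start coordinate for a span inside a gap slot.

    With ``left_gap`` set, the span sits exactly that many bp after the left
    gene (a planted proximal distance) while staying > window away from the
    right gene. Otherwise the span keeps > window distance from both
    flanking genes (open chromosome ends carry no constraint).
    """
    margin = window + 1
    if left_gap is not None:
        if not slot.left_gene:
            raise SimulationError("proximal placement needs a left flanking gene")
        start = slot.start + left_gap
        if start + span_len - 1 > slot.end - (margin if slot.right_gene else 0):
            raise SimulationError("gap too small for proximal placement")
        return start
    lo = slot.start + (margin if slot.left_gene else 0)
    hi = slot.end - (margin if slot.right_gene else 0) - span_len + 1
    if hi < lo:
        raise SimulationError(f"gap {slot.seqid}:{slot.start}-{slot.end} too small")
    return _ri(rng, lo, hi)


def generate_assembled(
    config: SimulationConfig,
    reference: AnnotationSet,
    gaps: list[GapSlot],
    rng: np.random.Generator,
) -> tuple[list[TranscriptModel], SyntheticTruth]:
    """Plant transcripts exercising every classification path.

    NATs are sub-exon antisense transcripts (overlap >= min_nat_overlap bp);
    incRNAs sit strictly inside introns with >= 10 bp margins; lincRNAs and
    putative mRNAs occupy intergenic slots (the designated proximal lincRNAs
    at planted gaps of at most the pairing window); short decoys exercise
    the length-exclusion path.
    """
    truth = SyntheticTruth()
    genes = [reference.genes[g] for g in sorted(reference.genes)]
    txs: list[TranscriptModel] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"A{counter:05d}"

    # reference-matching mRNAs
    for gi in sorted(rng.choice(len(genes), size=config.n_mrna_match, replace=False)):
        gene = genes[int(gi)]
        aid = new_id()
        txs.append(TranscriptModel(aid, gene.transcripts[0].exons))
        truth.category[aid] = "mRNA"
        truth.host_gene[aid] = gene.gene_id

    # NATs: opposite-strand sub-intervals of a host exon (distinct hosts)
    nat_host_idx = rng.choice(len(genes), size=config.n_nat, replace=False)
    nat_hosts = set()
    for gi in nat_host_idx:
        gene = genes[int(gi)]
        nat_hosts.add(gene.gene_id)
        exon = max(gene.transcripts[0].exons, key=lambda e: (e.length, -e.start))
        length = _ri(rng, max(200, config.min_nat_overlap), exon.length)
        offset = _ri(rng, 0, exon.length - length)
        strand = "-" if exon.strand == "+" else "+"
        aid = new_id()
        txs.append(TranscriptModel(aid, (
            GenomicInterval(exon.seqid, exon.start + offset, exon.start + offset + length - 1, strand),
        )))
        truth.category[aid] = "NAT"
        truth.host_gene[aid] = gene.gene_id

    # incRNAs: strictly inside the longest intron, >= 10 bp margins
    for gi in rng.choice(len(genes), size=config.n_inc, replace=False):
        gene = genes[int(gi)]
        tx = gene.transcripts[0]
        intron = max(introns_of(tx), key=lambda i: (i.length, -i.start))
        length = _ri(rng, 200, intron.length - 20)
        offset = _ri(rng, 10, intron.length - length - 10)
        strand = "+" if rng.random() < 0.5 else "-"
        aid = new_id()
        txs.append(TranscriptModel(aid, (
            GenomicInterval(intron.seqid, intron.start + offset, intron.start + offset + length - 1, strand),
        )))
        truth.category[aid] = "incRNA"
        truth.host_gene[aid] = gene.gene_id

    # intergenic transcripts, one per gap slot
    slot_order = [gaps[i] for i in rng.permutation(len(gaps))]
    proximal_slots = [s for s in slot_order if s.left_gene]
    other_slots = [s for s in slot_order if s not in proximal_slots]
    needed = config.n_linc + config.n_putative_mrna + (1 if config.n_short_decoys else 0)
    if needed > len(gaps):
        raise SimulationError(
            f"{needed} intergenic transcripts requested but only {len(gaps)} gap slots"
        )
    if config.n_linc_proximal > len(proximal_slots):
        raise SimulationError("not enough flanked gap slots for proximal lincRNAs")
    free_slots = proximal_slots[config.n_linc_proximal:] + other_slots

    def place_linc(j: int, slot: GapSlot, left_gap: int | None) -> str:
        total = _ri(rng, 200, 500)
        two_exon = j % 3 == 0
        span_len = total + 60 if two_exon else total
        strand = "+" if rng.random() < 0.5 else "-"
        start = _place_intergenic(slot, span_len, config.linc_window, rng, left_gap)
        aid = new_id()
        if two_exon:
            l1 = total // 2
            exons = (
                GenomicInterval(slot.seqid, start, start + l1 - 1, strand),
                GenomicInterval(slot.seqid, start + l1 + 60, start + span_len - 1, strand),
            )
        else:
            exons = (GenomicInterval(slot.seqid, start, start + span_len - 1, strand),)
        txs.append(TranscriptModel(aid, exons))
        truth.category[aid] = "lincRNA"
        return aid

    for j in range(config.n_linc_proximal):
        slot = proximal_slots[j]
        max_gap = min(config.linc_window, slot.length - 560 - config.linc_window - 1)
        left_gap = _ri(rng, 50, max_gap)
        aid = place_linc(j, slot, left_gap)
        truth.proximal[aid] = (slot.left_gene, left_gap)
    for j in range(config.n_linc_proximal, config.n_linc):
        place_linc(j, free_slots.pop(), None)

    for _ in range(config.n_putative_mrna):
        slot = free_slots.pop()
        length = _ri(rng, 300, 800)
        strand = "+" if rng.random() < 0.5 else "-"
        start = _place_intergenic(slot, length, config.linc_window, rng)
        aid = new_id()
        txs.append(TranscriptModel(aid, (
            GenomicInterval(slot.seqid, start, start + length - 1, strand),
        )))
        truth.category[aid] = "putative_mRNA"

    if config.n_short_decoys:
        # a 120-nt intergenic fragment and a 120-nt antisense fragment: both
        # below the lncRNA length rule, so both must be excluded as "short"
        slot = free_slots.pop()
        start = _place_intergenic(slot, 120, config.linc_window, rng)
        aid = new_id()
        txs.append(TranscriptModel(aid, (GenomicInterval(slot.seqid, start, start + 119, "+"),)))
        truth.category[aid] = "excluded"
        if config.n_short_decoys > 1:
            spare = [g for g in genes if g.gene_id not in nat_hosts]
            gene = spare[int(rng.integers(0, len(spare)))]
            exon = gene.transcripts[0].exons[0]
            strand = "-" if exon.strand == "+" else "+"
            aid = new_id()
            txs.append(TranscriptModel(aid, (
                GenomicInterval(exon.seqid, exon.start, exon.start + 119, strand),
            )))
            truth.category[aid] = "excluded"
            truth.host_gene[aid] = gene.gene_id

    txs.sort(key=lambda t: (t.seqid, t.interval.start, t.transcript_id))
    return txs, truth


def _sample_columns(config: SimulationConfig) -> list[str]:
    return [
        f"{cond}_{r}"
        for cond in ("NV", "V")
        for r in range(1, config.n_replicates + 1)
    ]


def generate_expression(
    config: SimulationConfig,
    reference: AnnotationSet,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """FPKM matrix with planted effects and planted pair patterns.

    Features are all reference gene ids plus every assembled transcript id.
    Pair quotas are honored by magnitude-``pair_effect_size`` effects with
    shared (coordinate) or opposing (antagonistic) signs; all other NATs,
    incRNAs and their host genes stay null so the planted pattern counts
    are exact. Remaining features receive effects with probability
    ``de_fraction``, drawn from ``effect_size_grid`` with random sign.
    Updates ``truth.effect`` and ``truth.pairs`` in place.
    """
    gene_ids = sorted(reference.genes)
    assembled_ids = sorted(truth.category)
    nats = [a for a in assembled_ids if truth.category[a] == "NAT"]
    incs = [a for a in assembled_ids if truth.category[a] == "incRNA"]

    protected: set[str] = set()
    eff = truth.effect
    mag = config.pair_effect_size

    nat_order = [nats[i] for i in rng.permutation(len(nats))]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = nat_order[cursor:cursor + n]
        cursor += n
        return out

    for i, nat in enumerate(take(config.n_pair_coordinate)):
        sign = 1.0 if i % 2 == 0 else -1.0
        eff[nat] = sign * mag
        eff[truth.host_gene[nat]] = sign * mag
        truth.pairs.append((nat, truth.host_gene[nat], "coordinate"))
    for i, nat in enumerate(take(config.n_pair_antagonistic)):
        sign = 1.0 if i % 2 == 0 else -1.0
        eff[nat] = sign * mag
        eff[truth.host_gene[nat]] = -sign * mag
        truth.pairs.append((nat, truth.host_gene[nat], "antagonistic"))
    for i, nat in enumerate(take(config.n_pair_lnc_only)):
        eff[nat] = (1.0 if i % 2 == 0 else -1.0) * mag
        truth.pairs.append((nat, truth.host_gene[nat], "lnc_only"))
    for i, nat in enumerate(take(config.n_pair_mrna_only)):
        eff[truth.host_gene[nat]] = (1.0 if i % 2 == 0 else -1.0) * mag
        truth.pairs.append((nat, truth.host_gene[nat], "mrna_only"))

    inc_order = [incs[i] for i in rng.permutation(len(incs))]
    for i, inc in enumerate(inc_order[:config.n_pair_inc_coordinate]):
        sign = 1.0 if i % 2 == 0 else -1.0
        eff[inc] = sign * mag
        eff[truth.host_gene[inc]] = sign * mag
        truth.pairs.append((inc, truth.host_gene[inc], "coordinate"))

    protected |= set(nats) | set(incs)
    protected |= {truth.host_gene[a] for a in nats + incs}

    grid = np.asarray(config.effect_size_grid, dtype=float)
    free = [g for g in gene_ids if g not in protected] + [
        a for a in assembled_ids
        if a not in protected and truth.category[a] in ("lincRNA", "putative_mRNA")
    ]
    for fid in free:
        if rng.random() < config.de_fraction:
            eff[fid] = float(rng.choice(grid)) * (1.0 if rng.random() < 0.5 else -1.0)
    # reference-matching assembled transcripts mirror their gene's response
    for aid in assembled_ids:
        if truth.category[aid] == "mRNA":
            eff.setdefault(aid, 0.0)
            eff[aid] = eff.get(truth.host_gene[aid], 0.0)

    cols = _sample_columns(config)
    features = gene_ids + assembled_ids
    m_mu, m_sd = config.mrna_log2_baseline
    l_mu, l_sd = config.lnc_log2_baseline
    baselines: dict[str, float] = {}
    for g in gene_ids:
        baselines[g] = float(rng.normal(m_mu, m_sd))
    for a in assembled_ids:
        cat = truth.category[a]
        if cat == "mRNA":
            baselines[a] = baselines[truth.host_gene[a]]
        elif cat == "putative_mRNA":
            baselines[a] = float(rng.normal(m_mu, m_sd))
        else:
            baselines[a] = float(rng.normal(l_mu, l_sd))

    values = np.empty((len(features), len(cols)))
    for i, fid in enumerate(features):
        effect = eff.get(fid, 0.0)
        for j, col in enumerate(cols):
            is_v = col.startswith("V")
            noise = rng.normal(0.0, config.replicate_noise_sd)
            values[i, j] = 2.0 ** (baselines[fid] + (effect if is_v else 0.0) + noise)
    frame = pd.DataFrame(values, index=pd.Index(features, name="feature_id"), columns=cols)
    return ExpressionMatrix(frame)


def generate_hits_and_terms(
    config: SimulationConfig,
    reference: AnnotationSet,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, TermMap]:
    """Protein-hit table and functional-term map consistent with the truth.

    Putative mRNAs receive hits at or below 1e-10; a few lincRNAs receive
    weak decoy hits strictly above the threshold. One planted term collects
    the strongly up-regulated genes and is flagged in
    ``truth.enriched_terms``.
    """
    rows = []
    putative = sorted(a for a, c in truth.category.items() if c == "putative_mRNA")
    lincs = sorted(a for a, c in truth.category.items() if c == "lincRNA")
    for i, aid in enumerate(putative):
        for h in range(2 if i % 3 == 0 else 1):
            ev = 10.0 ** -float(rng.uniform(15, 40))
            rows.append(_hit_row(aid, f"SP{i:04d}_{h}", ev, rng))
    for j, aid in enumerate(sorted(rng.choice(lincs, size=min(config.n_decoy_hits, len(lincs)), replace=False))):
        ev = 10.0 ** -float(rng.uniform(1, 8))  # always above the 1e-10 cutoff
        rows.append(_hit_row(aid, f"SPX{j:04d}", ev, rng))
    hits = pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ])

    gene_ids = sorted(reference.genes)
    up_genes = sorted(g for g in gene_ids if truth.effect.get(g, 0.0) > 2.0)
    genes_by_term: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    planted = set(up_genes)
    others = [g for g in gene_ids if g not in planted]
    pad = [others[i] for i in rng.permutation(len(others))[: max(0, 5 - len(planted))]]
    genes_by_term["T0000"] = frozenset(planted | set(pad))
    labels["T0000"] = "planted cold-response"
    namespaces["T0000"] = "BP"
    for t in range(1, config.n_terms):
        size = _ri(rng, *config.term_size)
        members = [gene_ids[i] for i in rng.choice(len(gene_ids), size=size, replace=False)]
        tid = f"T{t:04d}"
        genes_by_term[tid] = frozenset(members)
        labels[tid] = f"null term {t}"
        namespaces[tid] = ("BP", "MF", "CC")[t % 3]
    truth.enriched_terms = {"T0000"}
    return hits, TermMap(genes_by_term, labels, namespaces)


def _hit_row(qid: str, sid: str, evalue: float, rng: np.random.Generator) -> dict:
    alen = _ri(rng, 50, 200)
    return {
        "qseqid": qid, "sseqid": sid,
        "pident": round(float(rng.uniform(40, 95)), 2),
        "length": alen, "mismatch": _ri(rng, 0, 20), "gapopen": _ri(rng, 0, 3),
        "qstart": 1, "qend": alen, "sstart": 1, "send": alen,
        "evalue": float(f"{evalue:.3e}"), "bitscore": round(float(rng.uniform(40, 300)), 1),
    }


def generate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Build the full synthetic dataset from one seeded generator."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    reference, gaps = generate_annotation(config, rng)
    assembled, truth = generate_assembled(config, reference, gaps, rng)
    expression = generate_expression(config, reference, truth, rng)
    hits, terms = generate_hits_and_terms(config, reference, truth, rng)
    return SyntheticDataset(config, reference, gaps, assembled, expression, hits, terms, truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write every file dialect the pipeline consumes, plus the truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "assembled_gtf": outdir / "assembled.gtf",
        "expression_tsv": outdir / "expression.tsv",
        "hits_tsv": outdir / "hits.tsv",
        "terms_tsv": outdir / "terms.tsv",
        "truth_transcripts": outdir / "truth_transcripts.tsv",
        "truth_effects": outdir / "truth_effects.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
    }
    write_gtf(dataset.reference, paths["reference_gtf"])
    write_gtf(AnnotationSet.from_transcripts(dataset.assembled), paths["assembled_gtf"])
    dataset.expression.to_tsv(paths["expression_tsv"])
    dataset.hits.to_csv(paths["hits_tsv"], sep="\t", header=False, index=False)
    write_term_map(dataset.terms, paths["terms_tsv"])
    truth = dataset.truth
    pd.DataFrame(
        [
            {
                "transcript_id": a,
                "category": truth.category[a],
                "host_gene_id": truth.host_gene.get(a, ""),
                "proximal_gene": truth.proximal.get(a, ("", 0))[0],
                "proximal_distance": truth.proximal.get(a, ("", 0))[1],
            }
            for a in sorted(truth.category)
        ]
    ).to_csv(paths["truth_transcripts"], sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.effect.items()), columns=["feature_id", "effect"]
    ).to_csv(paths["truth_effects"], sep="\t", index=False)
    pd.DataFrame(
        truth.pairs, columns=["lnc_id", "mrna_gene_id", "pattern"]
    ).to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths


def simulate_planted_effects(
    n_signal: int,
    n_null: int,
    effect: float = 4.0,
    noise_sd: float = 0.25,
    baseline: float = 4.0,
    n_replicates: int = 2,
    rng: np.random.Generator | int | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """A bare planted-effect matrix for power/calibration studies.

    The first ``n_signal`` features carry the planted log2 *effect* in V;
    the rest are null. Returns the matrix and the per-feature truth effect.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = n_signal + n_null
    effects = np.concatenate([np.full(n_signal, effect), np.zeros(n_null)])
    cols = [f"{c}_{r}" for c in ("NV", "V") for r in range(1, n_replicates + 1)]
    is_v = np.array([c.startswith("V") for c in cols])
    noise = rng.normal(0.0, noise_sd, size=(n, len(cols)))
    log2_expr = baseline + np.outer(effects, is_v.astype(float)) + noise
    frame = pd.DataFrame(
        2.0 ** log2_expr,
        index=pd.Index([f"F{i:05d}" for i in range(n)], name="feature_id"),
        columns=cols,
    )
    truth = pd.Series(effects, index=frame.index, name="effect")
    return ExpressionMatrix(frame), truth


def simulate_pair_ratios(
    n: int,
    correlation: float,
    sd: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Bivariate-normal lncRNA/mRNA log2 ratios with a planted correlation."""
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cov = sd * sd * np.array([[1.0, correlation], [correlation, 1.0]])
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return pd.DataFrame(xy, columns=["lnc_log2_ratio", "mrna_log2_ratio"])
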