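"""lncRNA–mRNA pairing and joint vernalization-response pattern calls.

Each classified lncRNA is linked to partner protein-coding genes:

* NAT — the antisense-overlap host gene from its class code (distance 0);
* incRNA — the gene owning the containing intron (distance 0);
* lincRNA — genes whose span lies within ``linc_window`` bp (default 2 kb)
  of the lincRNA span on the same sequence, either strand; either every
  gene in the window or only the nearest one, per ``neighbor_policy``.

After differential-expression results are attached, each pair receives a
joint pattern: *coordinate* (both members significantly changed in the same
direction), *antagonistic* (both changed, opposite directions), *lnc_only*,
*mrna_only*, or *neither*. Pattern calls therefore require an FDR-level DE
call on both sides, mirroring the restriction of the published pair tables
to differentially expressed lncRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import AnnotationSet
from .classification import ClassifiedTranscript, LNC_CATEGORIES

logger = logging.getLogger(__name__)

RELATIONS = ("antisense_overlap", "intron_host", "proximal")
PATTERNS = ("coordinate", "antagonistic", "lnc_only", "mrna_only", "neither")


class PairingIntegrityError(ValueError):
    """A pairing referenced a gene absent from the annotation."""


@dataclass(frozen=True)
class PairingConfig:
    linc_window: int = 2000
    neighbor_policy: str = "all_within_window"  # or "nearest_only"

    def __post_init__(self) -> None:
        if self.linc_window < 0:
            raise ValueError("linc_window must be >= 0")
        if self.neighbor_policy not in ("all_within_window", "nearest_only"):
            raise ValueError(f"unknown neighbor_policy {self.neighbor_policy!r}")


@dataclass(frozen=True)
class PairRecord:
    """One lncRNA x gene link; a gene may appear in several records."""

    lnc_id: str
    lnc_category: str
    mrna_gene_id: str
    relation: str
    distance_bp: int
    lnc_log2_ratio: float | None = None
    mrna_log2_ratio: float | None = None
    lnc_direction: str = ""
    mrna_direction: str = ""
    pattern: str = ""


def expression_pattern(lnc_direction: str, mrna_direction: str) -> str:
    if lnc_direction != "ns" and mrna_direction != "ns":
        return "coordinate" if lnc_direction == mrna_direction else "antagonistic"
    if lnc_direction != "ns":
        return "lnc_only"
    if mrna_direction != "ns":
        return "mrna_only"
    return "neither"


def pair_lncrnas(
    classified: Iterable[ClassifiedTranscript],
    reference: AnnotationSet,
    config: PairingConfig | None = None,
) -> list[PairRecord]:
    """Build pair records (expression fields unset) for every lncRNA.

    lncRNAs without a partner (lincRNAs with no gene inside the window) are
    omitted with a logged count.
    """
    config = config or PairingConfig()
    pairs: list[PairRecord] = []
    n_unpaired = 0
    spans = [(g.gene_id, g.interval) for g in reference.genes.values()]
    for ct in classified:
        if ct.category not in LNC_CATEGORIES:
            continue
        if ct.category in ("NAT", "incRNA"):
            host = ct.class_code.host_gene_id
            if host not in reference.genes:
                raise PairingIntegrityError(
                    f"{ct.category} {ct.transcript.transcript_id} host gene "
                    f"{host!r} is absent from the annotation"
                )
            relation = "antisense_overlap" if ct.category == "NAT" else "intron_host"
            pairs.append(
                PairRecord(ct.transcript.transcript_id, ct.category, host, relation, 0)
            )
            continue
        # lincRNA: smallest span-to-span gap to any gene, either strand
        span = ct.transcript.interval
        candidates = []
        for gid, gspan in spans:
            gap = span.gap_to(gspan)
            if gap is not None and gap <= config.linc_window:
                candidates.append((gap, gid))
        if not candidates:
            n_unpaired += 1
            continue
        candidates.sort()
        if config.neighbor_policy == "nearest_only":
            candidates = candidates[:1]
        for gap, gid in candidates:
            pairs.append(
                PairRecord(ct.transcript.transcript_id, "lincRNA", gid, "proximal", gap)
            )
    if n_unpaired:
        logger.info("%d lincRNAs had no gene within %d bp", n_unpaired, config.linc_window)
    return pairs


def attach_expression(pairs: Iterable[PairRecord], de: pd.DataFrame) -> list[PairRecord]:
    """Populate ratio/direction/pattern fields from a DE result table.

    Pairs whose lncRNA or gene is missing from the DE table are dropped with
    a warning count.
    """
    out: list[PairRecord] = []
    n_dropped = 0
    for pair in pairs:
        if pair.lnc_id not in de.index or pair.mrna_gene_id not in de.index:
            n_dropped += 1
            continue
        lnc = de.loc[pair.lnc_id]
        mrna = de.loc[pair.mrna_gene_id]
        out.append(
            replace(
                pair,
                lnc_log2_ratio=float(lnc["log2_ratio"]),
                mrna_log2_ratio=float(mrna["log2_ratio"]),
                lnc_direction=str(lnc["direction"]),
                mrna_direction=str(mrna["direction"]),
                pattern=expression_pattern(str(lnc["direction"]), str(mrna["direction"])),
            )
        )
    if n_dropped:
        logger.warning("%d pairs dropped: member missing from DE table", n_dropped)
    return out


@dataclass
class PairSummary:
    """Counts per (category, lnc direction, mRNA direction) cell plus
    per-category correlations of the two log2(V/NV) ratios."""

    n_pairs: int
    cell_counts: dict[tuple[str, str, str], int]
    pattern_counts: dict[str, int]
    n_coordinate: int
    n_antagonistic: int
    correlations: dict[str, dict[str, float]]  # category -> {pearson_r, spearman_r, n}


def summarize_pairs(pairs: Sequence[PairRecord]) -> PairSummary:
    cells: dict[tuple[str, str, str], int] = {}
    patterns = {p: 0 for p in PATTERNS}
    for pair in pairs:
        key = (pair.lnc_category, pair.lnc_direction or "ns", pair.mrna_direction or "ns")
        cells[key] = cells.get(key, 0) + 1
        if pair.pattern:
            patterns[pair.pattern] += 1
    correlations: dict[str, dict[str, float]] = {}
    for category in sorted({p.lnc_category for p in pairs}):
        xy = [
            (p.lnc_log2_ratio, p.mrna_log2_ratio)
            for p in pairs
            if p.lnc_category == category
            and p.lnc_log2_ratio is not None
            and p.mrna_log2_ratio is not None
        ]
        if len(xy) >= 2:
            x, y = np.array(xy).T
            if np.std(x) > 0 and np.std(y) > 0:
                correlations[category] = {
                    "pearson_r": float(stats.pearsonr(x, y).statistic),
                    "spearman_r": float(stats.spearmanr(x, y).statistic),
                    "n": len(xy),
                }
    return PairSummary(
        n_pairs=len(pairs),
        cell_counts=cells,
        pattern_counts=patterns,
        n_coordinate=patterns["coordinate"],
        n_antagonistic=patterns["antagonistic"],
        correlations=correlations,
    )


PAIR_COLUMNS = [
    "lnc_id", "lnc_category", "mrna_gene_id", "relation", "distance_bp",
    "lnc_log2_ratio", "mrna_log2_ratio", "lnc_direction", "mrna_direction", "pattern",
]


def pairs_table(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) | {} for p in (pairs)], columns=PAIR_COLUMNS)


def pairs_from_table(df: pd.DataFrame) -> list[PairRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PairRecord(
                str(row.lnc_id), str(row.lnc_category), str(row.mrna_gene_id),
                str(row.relation), int(row.distance_bp),
                None if pd.isna(row.lnc_log2_ratio) else float(row.lnc_log2_ratio),
                None if pd.isna(row.mrna_log2_ratio) else float(row.mrna_log2_ratio),
                "" if pd.isna(row.lnc_direction) else str(row.lnc_direction),
                "" if pd.isna(row.mrna_direction) else str(row.mrna_direction),
                "" if pd.isna(row.pattern) else str(row.pattern),
            )
        )
    return out
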