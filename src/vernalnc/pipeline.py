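"""End-to-end orchestration: simulate -> classify -> DE -> pair -> enrich -> report.

Every stage writes its table under the output directory; the final
:class:`RunReport` re-counts those tables so the reported numbers are always
consistent with the emitted files. The run is fully deterministic under a
fixed seed and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_io, classification, enrichment, expression_de, pairing, synthetic_data
from .classification import ClassificationConfig
from .expression_de import DEConfig, ExpressionMatrix
from .pairing import PairingConfig
from .synthetic_data import SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One structured configuration for the whole pipeline."""

    seed: int = 42
    outdir: str = "vernalnc_out"
    reference_gtf: str | None = None
    assembled_gtf: str | None = None
    expression_tsv: str | None = None
    hits_tsv: str | None = None
    terms_tsv: str | None = None
    simulate: bool = False
    run_de: bool = True
    enrichment_fdr: float = 0.05
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    de: DEConfig = field(default_factory=DEConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (
            ("classification", ClassificationConfig),
            ("de", DEConfig),
            ("pairing", PairingConfig),
            ("simulation", SimulationConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in raw[key].items()
                }
                raw[key] = klass(**sub)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Counts recomputed from the emitted tables, plus a config echo."""

    seed: int
    outdir: str
    category_counts: dict[str, int]
    de_counts: dict[str, dict[str, int]]
    pattern_counts: dict[str, int]
    n_coordinate: int
    n_antagonistic: int
    n_enriched: dict[str, int]
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _stage(name):
    logger.info("stage %s starting", name)
    return time.perf_counter()


def _done(name, t0):
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)


def render_pair_report(pairs_df: pd.DataFrame, de: pd.DataFrame, pseudocount: float = 0.01) -> pd.DataFrame:
    """Publication-style table of differentially expressed NATs/incRNAs.

    One row per DE NAT/incRNA pair: lncRNA NV/V mean FPKM (2 decimals), the
    fold change recomputed from those printed values, then the partner gene
    with the same columns. Sorted by category, then descending |lncRNA
    log2 ratio|. Fold changes are computed from the rounded FPKM columns so
    that every printed log2 value is recomputable from the printed FPKM
    pair.
    """
    rows = []
    for rec in pairs_df.itertuples(index=False):
        if rec.lnc_category not in ("NAT", "incRNA"):
            continue
        if rec.lnc_direction not in ("up", "down"):
            continue
        if rec.lnc_id not in de.index or rec.mrna_gene_id not in de.index:
            continue
        lnc = de.loc[rec.lnc_id]
        mrna = de.loc[rec.mrna_gene_id]
        l_nv, l_v = round(lnc["mean_fpkm_nv"], 2), round(lnc["mean_fpkm_v"], 2)
        m_nv, m_v = round(mrna["mean_fpkm_nv"], 2), round(mrna["mean_fpkm_v"], 2)
        rows.append({
            "lnc_id": rec.lnc_id,
            "lnc_category": rec.lnc_category,
            "lnc_direction": rec.lnc_direction,
            "lnc_fpkm_nv": l_nv,
            "lnc_fpkm_v": l_v,
            "lnc_log2_ratio": round(
                expression_de.log2_fold_change(l_nv, l_v, pseudocount), 2
            ),
            "mrna_gene_id": rec.mrna_gene_id,
            "mrna_fpkm_nv": m_nv,
            "mrna_fpkm_v": m_v,
            "mrna_log2_ratio": round(
                expression_de.log2_fold_change(m_nv, m_v, pseudocount), 2
            ),
            "mrna_direction": rec.mrna_direction,
            "pattern": rec.pattern,
        })
    report = pd.DataFrame(rows, columns=[
        "lnc_id", "lnc_category", "lnc_direction", "lnc_fpkm_nv", "lnc_fpkm_v",
        "lnc_log2_ratio", "mrna_gene_id", "mrna_fpkm_nv", "mrna_fpkm_v",
        "mrna_log2_ratio", "mrna_direction", "pattern",
    ])
    if report.empty:
        return report
    report["abs_lfc"] = report["lnc_log2_ratio"].abs()
    report = (
        report.sort_values(["lnc_category", "abs_lfc"], ascending=[True, False], kind="stable")
        .drop(columns="abs_lfc")
        .reset_index(drop=True)
    )
    return report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every enabled stage, writing one TSV per stage plus report.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        t0 = _stage("simulate")
        sim_config = dataclasses.replace(config.simulation, seed=config.seed)
        dataset = synthetic_data.generate(sim_config)
        paths = synthetic_data.write_dataset(dataset, outdir / "simulated")
        config = dataclasses.replace(
            config,
            reference_gtf=str(paths["reference_gtf"]),
            assembled_gtf=str(paths["assembled_gtf"]),
            expression_tsv=str(paths["expression_tsv"]),
            hits_tsv=str(paths["hits_tsv"]),
            terms_tsv=str(paths["terms_tsv"]),
        )
        _done("simulate", t0)

    t0 = _stage("classify")
    reference = annotation_io.read_gtf(config.reference_gtf)
    assembled_set = annotation_io.read_gtf(config.assembled_gtf)
    assembled = assembled_set.transcripts()
    coding = (
        classification.load_coding_evidence(config.hits_tsv) if config.hits_tsv else {}
    )
    classified = classification.classify_transcripts(
        assembled, reference, coding, config.classification
    )
    class_table = classification.classification_table(classified)
    class_table.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    counts = classification.category_counts(classified)
    pd.DataFrame(sorted(counts.items()), columns=["category", "count"]).to_csv(
        outdir / "category_counts.tsv", sep="\t", index=False
    )
    _done("classify", t0)

    de = None
    if config.run_de and config.expression_tsv:
        t0 = _stage("de")
        matrix = ExpressionMatrix.read_tsv(config.expression_tsv)
        de = expression_de.differential_expression(matrix, config.de)
        de.to_csv(outdir / "de.tsv", sep="\t")
        cats = {ct.transcript.transcript_id: ct.category for ct in classified}
        summary, pairwise = expression_de.compare_category_expression(
            matrix,
            cats | {g: "mRNA" for g in reference.genes},
            pseudocount=config.de.pseudocount,
        )
        summary.to_csv(outdir / "category_expression.tsv", sep="\t", index=False)
        pairwise.to_csv(outdir / "category_expression_tukey.tsv", sep="\t", index=False)
        _done("de", t0)
    else:
        logger.warning("DE stage disabled or no expression input: pair patterns will be absent")

    t0 = _stage("pair")
    pairs = pairing.pair_lncrnas(classified, reference, config.pairing)
    if de is not None:
        pairs = pairing.attach_expression(pairs, de)
    pairs_df = pairing.pairs_table(pairs)
    pairs_df.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    _done("pair", t0)

    n_enriched = {"up": 0, "down": 0}
    if de is not None and config.terms_tsv:
        t0 = _stage("enrich")
        terms = enrichment.load_term_map(config.terms_tsv)
        gene_ids = set(reference.genes)
        supported_genes = {
            str(f) for f in de.index[de["supported"]] if str(f) in gene_ids
        }
        up, down = enrichment.regulated_gene_lists(
            de,
            features=supported_genes,
            log2_threshold=config.de.high_fc_threshold,
            fdr_threshold=config.de.fdr_threshold,
        )
        for name, gene_list in (("up", up), ("down", down)):
            result = enrichment.enrich(
                gene_list, supported_genes, terms, config.enrichment_fdr
            )
            result.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
            n_enriched[name] = int(result["enriched"].sum()) if not result.empty else 0
        _done("enrich", t0)

    t0 = _stage("report")
    if de is not None:
        report_table = render_pair_report(pairs_df, de, config.de.pseudocount)
    else:
        report_table = render_pair_report(pairs_df, pd.DataFrame(
            columns=["mean_fpkm_nv", "mean_fpkm_v", "log2_ratio", "direction"]
        ))
    report_table.to_csv(outdir / "pair_report.tsv", sep="\t", index=False, float_format="%.2f")

    # recount everything from the emitted tables
    class_back = pd.read_csv(outdir / "classification.tsv", sep="\t").fillna("")
    category_counts = class_back["category"].value_counts().to_dict()
    de_counts: dict[str, dict[str, int]] = {}
    if de is not None:
        de_back = pd.read_csv(outdir / "de.tsv", sep="\t", index_col=0)
        cat_map = dict(zip(class_back["transcript_id"], class_back["category"]))
        cat_map.update({g: "mRNA" for g in reference.genes})
        joined = de_back.assign(
            category=[cat_map.get(str(i)) for i in de_back.index]
        ).dropna(subset=["category"])
        for cat, grp in joined.groupby("category"):
            de_counts[cat] = {
                d: int((grp["direction"] == d).sum()) for d in ("up", "down", "ns")
            }
    pairs_back = pd.read_csv(outdir / "pairs.tsv", sep="\t").fillna("")
    pattern_counts = {
        p: int((pairs_back["pattern"] == p).sum()) for p in pairing.PATTERNS
    }
    report = RunReport(
        seed=config.seed,
        outdir=str(outdir),
        category_counts={k: int(v) for k, v in sorted(category_counts.items())},
        de_counts=de_counts,
        pattern_counts=pattern_counts,
        n_coordinate=pattern_counts["coordinate"],
        n_antagonistic=pattern_counts["antagonistic"],
        n_enriched=n_enriched,
        config=config.to_dict(),
    )
    report.to_json(outdir / "report.json")
    _done("report", t0)
    return report
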