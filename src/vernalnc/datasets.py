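"""Bundled example data.

``load_vernalization_pairs`` returns a published reference set of
differentially expressed NAT/incRNA–mRNA pairs from a *Brassica rapa*
vernalization transcriptome: per pair, the lncRNA's mean FPKM before (NV)
and after four weeks of cold treatment (V), the printed log2(V/NV) fold
change, the covering protein-coding gene with the same columns, and the
published direction calls. The set contains 18 NAT pairs (11 with
up-regulated, 7 with down-regulated NATs) and 2 incRNA pairs; it is the
worked example used throughout the documentation and the acceptance checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .pairing import PairRecord, expression_pattern


def load_vernalization_pairs() -> pd.DataFrame:
    """The B. rapa vernalization NAT/incRNA pair reference table."""
    ref = resources.files("vernalnc.data") / "brapa_vernalization_pairs.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def vernalization_pair_records() -> list[PairRecord]:
    """The same table as :class:`~vernalnc.pairing.PairRecord` objects.

    Directions come from the published calls; patterns are recomputed from
    those directions. NAT pairs use the antisense-overlap relation, incRNA
    pairs the intron-host relation (both distance 0 by definition).
    """
    df = load_vernalization_pairs()
    records = []
    for row in df.itertuples(index=False):
        relation = "antisense_overlap" if row.lnc_category == "NAT" else "intron_host"
        records.append(
            PairRecord(
                lnc_id=row.lnc_id,
                lnc_category=row.lnc_category,
                mrna_gene_id=row.mrna_gene_id,
                relation=relation,
                distance_bp=0,
                lnc_log2_ratio=float(row.lnc_log2_fc),
                mrna_log2_ratio=float(row.mrna_log2_fc),
                lnc_direction=row.lnc_direction,
                mrna_direction=row.mrna_direction,
                pattern=expression_pattern(row.lnc_direction, row.mrna_direction),
            )
        )
    return records
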