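"""Hypergeometric functional-term enrichment with BH FDR control.

Given a regulated gene list drawn from a population of N genes, a term
annotating K population genes and covering k of the n list genes is scored
with the upper-tail hypergeometric probability P(X >= k), accumulated in
log space for numerical stability. Benjamini–Hochberg correction runs
across all tested terms (k >= 1) and a term is *enriched* when its q-value
falls below the FDR threshold (5% by default). The background population
defaults, at the pipeline level, to the expression-supported genes — the
universe that was actually eligible for the list — rather than the whole
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .expression_de import bh_fdr


@dataclass
class TermMap:
    """Functional terms: term id -> gene set, with optional labels/namespaces."""

    genes_by_term: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes_by_term = {t: frozenset(g) for t, g in self.genes_by_term.items()}
        for term, genes in self.genes_by_term.items():
            if not genes:
                raise ValueError(f"term {term} has an empty gene set")


def load_term_map(path) -> TermMap:
    """Read a gene->term TSV (columns gene_id, term_id[, namespace, label])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genes: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for row in df.itertuples(index=False):
        genes.setdefault(row.term_id, set()).add(row.gene_id)
        if getattr(row, "label", ""):
            labels[row.term_id] = row.label
        if getattr(row, "namespace", ""):
            namespaces[row.term_id] = row.namespace
    return TermMap({t: frozenset(g) for t, g in genes.items()}, labels, namespaces)


def write_term_map(terms: TermMap, path) -> None:
    rows = [
        {
            "gene_id": gene,
            "term_id": term,
            "namespace": terms.namespaces.get(term, ""),
            "label": terms.labels.get(term, ""),
        }
        for term in sorted(terms.genes_by_term)
        for gene in sorted(terms.genes_by_term[term])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id", "namespace", "label"]).to_csv(
        path, sep="\t", index=False
    )


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    log_p = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(log_p))))


ENRICHMENT_COLUMNS = [
    "term_id", "label", "namespace", "population_size", "annotated_in_population",
    "list_size", "annotated_in_list", "p_value", "fdr", "enriched",
]


def enrich(
    gene_list: set[str],
    population: set[str],
    terms: TermMap,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Score every term with k >= 1 list genes; BH across tested terms.

    Term gene sets are intersected with the population before counting, so
    genes annotated outside the tested universe do not inflate K. Raises if
    the gene list is not a subset of the population. The result is sorted by
    (fdr, p_value, term_id) and thus independent of term iteration order.
    """
    gene_list = set(gene_list)
    population = set(population)
    stray = sorted(gene_list - population)
    if stray:
        shown = ", ".join(stray[:10]) + ("..." if len(stray) > 10 else "")
        raise ValueError(f"gene_list not a subset of population: {shown}")
    N, n = len(population), len(gene_list)
    rows = []
    for term in sorted(terms.genes_by_term):
        genes = terms.genes_by_term[term] & population
        K = len(genes)
        k = len(genes & gene_list)
        if k == 0:
            continue
        rows.append({
            "term_id": term,
            "label": terms.labels.get(term, ""),
            "namespace": terms.namespaces.get(term, ""),
            "population_size": N,
            "annotated_in_population": K,
            "list_size": n,
            "annotated_in_list": k,
            "p_value": hypergeometric_upper_tail(N, K, n, k),
        })
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-2])
    if df.empty:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    df["enriched"] = df["fdr"] < fdr_threshold
    return df.sort_values(["fdr", "p_value", "term_id"], kind="stable").reset_index(drop=True)


def regulated_gene_lists(
    de: pd.DataFrame,
    features: set[str] | None = None,
    log2_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Highly up-/down-regulated gene lists: |log2 ratio| > threshold at FDR.

    *features* optionally restricts the DE table to a universe (e.g. gene
    ids, excluding lncRNA transcript rows).
    """
    sub = de if features is None else de.loc[de.index.intersection(sorted(features))]
    sig = sub["fdr"] < fdr_threshold
    up = set(sub.index[sig & (sub["log2_ratio"] > log2_threshold)].astype(str))
    down = set(sub.index[sig & (sub["log2_ratio"] < -log2_threshold)].astype(str))
    return up, down
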