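"""Term-enrichment statistics for duplicated/deleted gene sets.

Per-term one-sided Fisher over-representation tests (hypergeometric upper
tail), the elim decorrelation pass over the term DAG (genes of a
significant term are removed from its ancestors before those are tested),
and Benjamini-Hochberg FDR. The ontology itself is an input: a child ->
parent edge table and a gene -> term annotation table, both plain TSV, with
annotations propagated to ancestors (the true-path rule) before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet, _overlap_mask, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class TermGraph:
    """A GO-style DAG with gene annotations propagated to ancestors."""

    graph: nx.DiGraph  # edges child -> parent
    annotations: dict[str, set[str]]  # term -> genes (propagated)

    @classmethod
    def from_tables(
        cls, gene2term: pd.DataFrame, edges: pd.DataFrame | None = None
    ) -> "TermGraph":
        """Build from (gene, term) rows and optional (child, parent) rows.

        Terms mentioned only in edges carry empty annotation until
        propagation fills them from descendants.
        """
        g = nx.DiGraph()
        direct: dict[str, set[str]] = {}
        for row in gene2term.itertuples(index=False):
            gene, term = str(row[0]), str(row[1])
            direct.setdefault(term, set()).add(gene)
            g.add_node(term)
        if edges is not None:
            for row in edges.itertuples(index=False):
                child, parent = str(row[0]), str(row[1])
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term graph contains a cycle")
        # true-path propagation: every ancestor inherits its descendants' genes
        annotations = {t: set(direct.get(t, set())) for t in g.nodes}
        for term in nx.topological_sort(g):  # children before parents
            for parent in g.successors(term):
                annotations[parent] |= annotations[term]
        return cls(g, annotations)

    @classmethod
    def from_files(cls, gene2term_path: str | Path, edges_path: str | Path | None = None) -> "TermGraph":
        g2t = pd.read_csv(gene2term_path, sep="\t", header=None, comment="#")
        edges = (
            pd.read_csv(edges_path, sep="\t", header=None, comment="#")
            if edges_path
            else None
        )
        return cls.from_tables(g2t, edges)

    def terms(self) -> list[str]:
        return list(self.graph.nodes)


def fisher_term_test(term_genes: set[str], study: set[str], universe: set[str]) -> float:
    """One-sided over-representation p: hypergeometric upper tail
    P(X >= observed hits) for drawing |study| genes from the universe."""
    if not universe:
        raise ValueError("empty universe")
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    term_in_universe = term_genes & universe
    hits = len(term_in_universe & study)
    M, K, n = len(universe), len(term_in_universe), len(study)
    if hits == 0:
        return 1.0
    return float(hypergeom.sf(hits - 1, M, K, n))


def elim_enrichment(
    graph: TermGraph,
    study: set[str],
    universe: set[str],
    alpha_elim: float = 0.01,
) -> pd.DataFrame:
    """Per-term raw Fisher and elim p-values plus BH q-values.

    Terms are processed leaves-first (reverse-topological over child ->
    parent edges); a term whose current-gene-set Fisher p falls below
    ``alpha_elim`` has its annotated genes removed from all its ancestors'
    gene sets before those are tested. ``alpha_elim = 0`` disables
    elimination, reducing elim p to the raw Fisher p everywhere. BH q is
    emitted for both columns (the raw-p column is the conventional one to
    threshold).
    """
    study = set(study)
    universe = set(universe)
    current = {t: set(g) for t, g in graph.annotations.items()}
    raw_p: dict[str, float] = {}
    elim_p: dict[str, float] = {}
    order = list(nx.topological_sort(graph.graph))  # children before parents
    for term in order:
        raw_p[term] = fisher_term_test(graph.annotations[term], study, universe)
        p = fisher_term_test(current[term], study, universe)
        elim_p[term] = p
        if p < alpha_elim:
            for anc in nx.descendants(graph.graph, term):  # ancestors in the DAG
                current[anc] -= graph.annotations[term]
    rows = []
    for term in sorted(graph.annotations):
        ann_u = graph.annotations[term] & universe
        rows.append(
            (
                term,
                len(ann_u & study),
                len(study),
                len(ann_u),
                len(universe),
                raw_p[term],
                elim_p[term],
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "hits", "study_size", "term_size", "universe_size", "p_raw", "p_elim"],
    )
    if len(df):
        df["q_raw"] = bh_fdr(df["p_raw"].to_numpy())
        df["q_elim"] = bh_fdr(df["p_elim"].to_numpy())
    return df.sort_values(["p_elim", "p_raw", "term"]).reset_index(drop=True)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, order preserved."""
    p = np.asarray(pvalues, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return np.minimum(multipletests(p, method="fdr_bh")[1], 1.0)


def genes_overlapping_sites(
    sites: pd.DataFrame, genes: IntervalSet
) -> set[str]:
    """Gene names whose interval overlaps >= 1 bp of any CNV site."""
    if not len(sites) or not len(genes):
        return set()
    site_iv = merge_intervals(IntervalSet(sites[["chrom", "start", "end"]])).by_chrom()
    out: set[str] = set()
    for chrom, sub in genes.df.groupby("chrom"):
        if chrom not in site_iv:
            continue
        b_s, b_e = site_iv[chrom]
        mask = _overlap_mask(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64), b_s, b_e
        )
        out |= set(sub.loc[mask, "name"].astype(str))
    return out


def differential_enrichment(
    sites: pd.DataFrame,
    groups: pd.Series,
    genes: IntervalSet,
    graph: TermGraph,
    exclusive_group: str = "wild",
    alpha_elim: float = 0.01,
) -> pd.DataFrame:
    """Enrichment of genes hit by CNV sites carried exclusively by one group.

    The study set is the genes overlapped by sites whose carriers all belong
    to ``exclusive_group`` (the CNV diversity lost outside that group); the
    universe is every annotated gene. Empty study sets yield an empty table
    with a warning.
    """
    universe = set().union(*graph.annotations.values()) if graph.annotations else set()
    if not len(sites):
        logger.warning("no sites: empty differential enrichment")
        return pd.DataFrame()
    exclusive = []
    for row in sites.itertuples():
        carriers = [c for c in str(row.carriers).split(",") if c]
        if carriers and all(groups.get(c) == exclusive_group for c in carriers):
            exclusive.append(row.Index)
    study = genes_overlapping_sites(sites.loc[exclusive], genes) & universe
    if not study:
        logger.warning("no %s-exclusive CNV genes: empty enrichment table", exclusive_group)
        return pd.DataFrame()
    return elim_enrichment(graph, study, universe, alpha_elim)
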