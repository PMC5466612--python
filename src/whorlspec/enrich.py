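"""GO-term enrichment by the Kolmogorov-Smirnov rank test and the
resemblance analysis of comparisons.

Genes are ranked by a per-gene score (by convention the raw differential-
expression p-value: smaller = more significant).  For each term the scores
of annotated genes are compared with those of all other genes by a
one-sided two-sample KS test oriented so that a small p-value means the
annotated genes concentrate at the significant end of the ranking.  Per
comparison, BH-adjusted significant terms are consolidated into a
comparisons x terms matrix of -log10(adjusted p), which is clustered by
furthest-neighbor (complete) linkage to reveal which organ-pair comparisons
resemble one another functionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .cluster import Dendrogram, agglomerate, euclidean_distance_matrix
from .deg import bh_adjust

log = logging.getLogger(__name__)

MIN_GENES = 5
SIGNIFICANCE_ALPHA = 0.05
HIGHLY_ENRICHED_CUTOFF = 1e-5


@dataclass
class EnrichmentResult:
    """Per-term KS enrichment for one comparison.

    ``table`` columns: ks_stat, pvalue, adj_p, n_genes (indexed by term).
    """

    comparison: str
    table: pd.DataFrame

    def significant_terms(self, alpha: float = SIGNIFICANCE_ALPHA) -> set[str]:
        return set(self.table.index[self.table["adj_p"] < alpha])


def _invert_annotation(annotation: dict[str, set[str]]) -> dict[str, set[str]]:
    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        for t in terms:
            term_to_genes.setdefault(t, set()).add(gene)
    return term_to_genes


def ks_enrichment(gene_scores: pd.Series, annotation: dict[str, set[str]],
                  min_genes: int = MIN_GENES, comparison: str = "comparison",
                  method: str = "auto") -> EnrichmentResult:
    """One-sided two-sample KS enrichment of every annotated term.

    ``gene_scores`` must cover the annotation's gene universe; scores are
    oriented so that SMALL values are significant (DEG p-values).  Terms
    annotating fewer than ``min_genes`` genes in the universe are dropped;
    a term covering the whole universe is skipped (empty complement).
    ``method`` is passed to scipy's ks_2samp ("auto" switches to the exact
    small-sample computation when warranted).
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    universe = set(gene_scores.index)
    term_to_genes = _invert_annotation(annotation)
    rows = {}
    for term in sorted(term_to_genes):
        genes = term_to_genes[term] & universe
        if len(genes) < min_genes:
            continue
        rest = universe - genes
        if not rest:
            log.info("term %s annotates the whole universe; skipped", term)
            continue
        in_scores = gene_scores.loc[sorted(genes)].to_numpy(dtype=float)
        out_scores = gene_scores.loc[sorted(rest)].to_numpy(dtype=float)
        # alternative="greater": the annotated sample's empirical CDF lies
        # above the rest, i.e. annotated genes concentrate at the
        # significant (small-score) end of the ranking
        res = ks_2samp(in_scores, out_scores, alternative="greater", method=method)
        rows[term] = (float(res.statistic), float(max(res.pvalue, np.finfo(float).tiny)),
                      len(genes))
    if rows:
        table = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=["ks_stat", "pvalue", "n_genes"])
        table["adj_p"] = bh_adjust(table["pvalue"].to_numpy())
        table = table[["ks_stat", "pvalue", "adj_p", "n_genes"]]
    else:
        table = pd.DataFrame(columns=["ks_stat", "pvalue", "adj_p", "n_genes"])
    table.index.name = "term"
    return EnrichmentResult(comparison=comparison, table=table)


def significant_terms(result: EnrichmentResult,
                      alpha: float = SIGNIFICANCE_ALPHA) -> set[str]:
    """Terms with BH-adjusted p below alpha."""
    return result.significant_terms(alpha)


def build_comparison_matrix(results: list[EnrichmentResult],
                            alpha: float = SIGNIFICANCE_ALPHA,
                            binary: bool = False) -> pd.DataFrame:
    """Comparisons x significant-terms matrix.

    Entries are -log10(adjusted p) for terms significant in that comparison
    (or 1/0 presence when ``binary``), 0 elsewhere.  Columns are the union of
    per-comparison significant sets, sorted; rows follow input order.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 comparisons")
    ids = [r.comparison for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate comparison ids in {ids}")
    sig_sets = {r.comparison: r.significant_terms(alpha) for r in results}
    all_terms = sorted(set().union(*sig_sets.values()))
    mat = pd.DataFrame(0.0, index=ids, columns=all_terms)
    for r in results:
        if not sig_sets[r.comparison]:
            log.warning("comparison %s has no significant terms (zero row)",
                        r.comparison)
        for term in sig_sets[r.comparison]:
            mat.loc[r.comparison, term] = (
                1.0 if binary else -np.log10(r.table.loc[term, "adj_p"]))
    return mat


def cluster_comparisons(matrix: pd.DataFrame) -> Dendrogram:
    """Furthest-neighbor clustering of comparisons by their enrichment rows."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 comparisons to cluster")
    dist = euclidean_distance_matrix(matrix.T)
    return agglomerate(dist, method="complete")


def highly_enriched_screen(results: list[EnrichmentResult],
                           cutoff: float = HIGHLY_ENRICHED_CUTOFF) -> pd.DataFrame:
    """Binary terms x comparisons presence table at a stringent RAW KS p cutoff.

    A term appears when its raw KS p <= cutoff in at least one comparison;
    columns keep the input comparison order.
    """
    cols = [r.comparison for r in results]
    hits: dict[str, dict[str, int]] = {}
    for r in results:
        below = r.table.index[r.table["pvalue"] <= cutoff]
        for term in below:
            hits.setdefault(term, {})[r.comparison] = 1
    table = pd.DataFrame(0, index=sorted(hits), columns=cols, dtype=int)
    for term, marks in hits.items():
        for comp in marks:
            table.loc[term, comp] = 1
    table.index.name = "term"
    return table
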