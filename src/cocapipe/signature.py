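"""Discriminating-signature derivation between integrated clusters.

Differential expression between two clusters (or one cluster versus the
rest) with Benjamini-Hochberg control, correlation-based filtering of genes
tracking the signature features, and Fisher-exact gene-set enrichment of the
resulting lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, rankdata, ttest_ind
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DiffExpResult",
    "diffexp_two_group",
    "diffexp_one_vs_rest",
    "spearman_filter",
    "geneset_enrichment",
]


@dataclass
class DiffExpResult:
    """Per-feature differential-expression table with threshold flags."""

    table: pd.DataFrame  # statistic, p_raw, p_adj, log2fc, passed
    test: str
    p_thresh: float
    fc_thresh: float | None

    @property
    def passing(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


def diffexp_two_group(
    expr: pd.DataFrame,
    group1: list | pd.Index,
    group2: list | pd.Index,
    test: str = "wilcoxon",
    p_thresh: float = 0.01,
    fc_thresh: float | None = 1.0,
) -> DiffExpResult:
    """Two-sided per-feature test between two sample groups with BH control.

    ``expr`` is features x samples on log2 scale, so the fold change is the
    difference of group means: log2FC = mean(group1) - mean(group2). A
    feature passes when its BH-adjusted p-value is below ``p_thresh`` and,
    if ``fc_thresh`` is set, |log2FC| exceeds it. Features constant across
    both groups get p = 1.
    """
    if test not in ("wilcoxon", "t"):
        raise ValueError(f"unknown test {test!r}")
    g1 = pd.Index(group1)
    g2 = pd.Index(group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    if len(g1.intersection(g2)) > 0:
        raise ValueError("groups must be disjoint")

    x1 = expr[g1].to_numpy(dtype=float)
    x2 = expr[g2].to_numpy(dtype=float)
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)

    stats = np.empty(expr.shape[0])
    pvals = np.empty(expr.shape[0])
    for i in range(expr.shape[0]):
        a, b = x1[i], x2[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            stats[i] = np.nan
            pvals[i] = 1.0
            logger.debug("feature %s constant in both groups", expr.index[i])
            continue
        if test == "wilcoxon":
            res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        else:
            res = ttest_ind(a, b, equal_var=False)
        stats[i] = res.statistic
        pvals[i] = res.pvalue

    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    passed = p_adj < p_thresh
    if fc_thresh is not None:
        passed &= np.abs(log2fc) > fc_thresh
    table = pd.DataFrame(
        {
            "statistic": stats,
            "p_raw": pvals,
            "p_adj": p_adj,
            "log2fc": log2fc,
            "passed": passed,
        },
        index=expr.index,
    )
    return DiffExpResult(table, test, p_thresh, fc_thresh)


def diffexp_one_vs_rest(
    expr: pd.DataFrame,
    labels: pd.Series,
    test: str = "wilcoxon",
    p_thresh: float = 0.05,
    fc_thresh: float | None = None,
) -> dict[str, DiffExpResult]:
    """Each cluster versus the pooled rest; BH within each comparison.

    Singleton clusters are skipped with a warning.
    """
    labels = labels.dropna()
    clusters = sorted(labels.unique(), key=str)
    if len(clusters) < 2:
        raise ValueError("at least two clusters required")
    out: dict[str, DiffExpResult] = {}
    for cluster in clusters:
        members = labels.index[labels == cluster]
        rest = labels.index[labels != cluster]
        if len(members) < 2:
            logger.warning("diffexp_one_vs_rest: singleton cluster %r skipped", cluster)
            continue
        out[str(cluster)] = diffexp_two_group(
            expr, members, rest, test=test, p_thresh=p_thresh, fc_thresh=fc_thresh
        )
    return out


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, x)


def spearman_filter(
    feature_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Retain genes whose best |Spearman rho| against any feature exceeds a cutoff.

    ``feature_expr`` (e.g. signature miRNAs) and ``gene_expr`` (mRNA) are
    features x samples; correlations use the shared samples with average
    ranks for ties. Returns the retained genes with their best-correlated
    partner feature and the signed rho.
    """
    shared = feature_expr.columns.intersection(gene_expr.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between the two matrices")
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, got {len(shared)}")

    f = _rank_rows(feature_expr[shared].to_numpy(dtype=float))
    g = _rank_rows(gene_expr[shared].to_numpy(dtype=float))

    def standardize(r: np.ndarray) -> np.ndarray:
        mu = r.mean(axis=1, keepdims=True)
        sd = r.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf  # constant rows correlate 0 with everything
        return (r - mu) / sd

    fz = standardize(f)
    gz = standardize(g)
    rho = gz @ fz.T / len(shared)  # genes x features

    best = np.abs(rho).argmax(axis=1)
    best_rho = rho[np.arange(rho.shape[0]), best]
    keep = np.abs(best_rho) > threshold
    out = pd.DataFrame(
        {
            "gene": gene_expr.index[keep],
            "feature": feature_expr.index[best[keep]],
            "rho": best_rho[keep],
        }
    ).set_index("gene")
    return out.sort_values("rho", key=np.abs, ascending=False)


def geneset_enrichment(
    hit_genes: list | pd.Index,
    universe_genes: list | pd.Index,
    gene_sets: dict[str, list],
    correction: str = "bh",
) -> pd.DataFrame:
    """One-sided Fisher-exact enrichment of a hit list in each gene set.

    For each set, the 2x2 table of (hit, non-hit) x (in set, not in set) over
    the universe is tested for over-representation; p-values are BH-adjusted
    across sets.
    """
    hits = pd.Index(pd.unique(pd.Index(hit_genes)))
    universe = pd.Index(pd.unique(pd.Index(universe_genes)))
    stray = hits.difference(universe)
    if len(stray) > 0:
        raise ValueError(f"hit genes absent from universe: {sorted(stray)}")
    rows = []
    for name, genes in gene_sets.items():
        members = universe.intersection(pd.Index(genes))
        if len(members) == 0:
            logger.warning("geneset_enrichment: set %r has no universe genes", name)
        a = len(hits.intersection(members))
        b = len(hits) - a
        c = len(members) - a
        d = len(universe) - len(hits) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"set": name, "overlap": a, "set_size": len(members), "p_raw": float(p)}
        )
    out = pd.DataFrame(rows).set_index("set")
    if correction == "bh":
        _, p_adj, _, _ = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")
        out["p_adj"] = p_adj
    elif correction == "none":
        out["p_adj"] = out["p_raw"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out.sort_values("p_raw")
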