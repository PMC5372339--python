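"""Association of integrated clusters with subtype levels and clinical data.

The phi coefficient — the Pearson correlation of two 0/1 membership vectors —
quantifies how strongly each input subtype level tracks each integrated
cluster; chi-squared tests relate cluster membership to categorical clinical
variables with Bonferroni control over the test family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .integration import ClassificationLayer

logger = logging.getLogger(__name__)

__all__ = ["membership_phi", "phi_coefficient", "chisq_clinical"]


def phi_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two binary vectors; NaN when either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def membership_phi(
    cluster_labels: pd.Series,
    layers: list[ClassificationLayer],
    na_policy: str = "zero",
) -> pd.DataFrame:
    """Rank every subtype level by its phi correlation with each cluster.

    Each sample is coded 0/1 for membership of every integrated cluster and
    every (layer, level); phi is the Pearson correlation of the two binary
    vectors. Under ``na_policy="zero"`` a sample missing a layer is coded 0
    for all of that layer's levels (it "does not belong" to any of them);
    under ``"complete"`` such samples are dropped from that layer's
    correlations. Levels are ranked descending per cluster, with undefined
    (constant-vector) correlations reported as NaN and ranked last.
    """
    if na_policy not in ("zero", "complete"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    cluster_labels = cluster_labels.dropna()
    rows = []
    for cluster in sorted(cluster_labels.unique(), key=str):
        cvec_full = (cluster_labels == cluster).astype(int)
        for layer in layers:
            common = cluster_labels.index.intersection(layer.labels.index)
            if len(common) == 0:
                raise ValueError(
                    f"no overlapping samples between clusters and layer {layer.name!r}"
                )
            lab = layer.labels.reindex(cluster_labels.index)
            for level in layer.vocabulary:
                lvec = (lab.astype(object) == level).astype(int)
                if na_policy == "complete":
                    mask = lab.notna()
                    r = phi_coefficient(cvec_full[mask], lvec[mask])
                    n_used = int(mask.sum())
                else:
                    r = phi_coefficient(cvec_full, lvec)
                    n_used = len(cvec_full)
                rows.append(
                    {
                        "cluster": cluster,
                        "layer": layer.name,
                        "level": str(level),
                        "r": r,
                        "n": n_used,
                    }
                )
    out = pd.DataFrame(rows)
    out["rank"] = (
        out.groupby("cluster")["r"]
        .rank(ascending=False, method="first", na_option="bottom")
        .astype(int)
    )
    return out.sort_values(["cluster", "rank"]).reset_index(drop=True)


def chisq_clinical(
    cluster_labels: pd.Series,
    clinical: pd.DataFrame,
    variables: list[str] | None = None,
    correction: str = "bonferroni",
    continuity: bool = False,
) -> pd.DataFrame:
    """Chi-squared association of each cluster with each clinical variable.

    For every (cluster, variable) pair, a 2 x V contingency table of cluster
    membership against the variable's categories is tested (no continuity
    correction by default). P-values are Bonferroni-adjusted across the whole
    family of performed tests. Variables with a single observed category are
    skipped with a warning; tables with any expected count below 5 are
    flagged in the ``low_expected`` column.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    variables = variables if variables is not None else list(clinical.columns)
    cluster_labels = cluster_labels.dropna()
    common = cluster_labels.index.intersection(clinical.index)
    cl = cluster_labels.loc[common]

    rows = []
    for cluster in sorted(cl.unique(), key=str):
        member = (cl == cluster).astype(int)
        for var in variables:
            v = clinical.loc[common, var].dropna()
            cats = v.unique()
            if len(cats) < 2:
                logger.warning(
                    "chisq_clinical: variable %r has one observed category; skipped", var
                )
                continue
            table = pd.crosstab(member.loc[v.index], v)
            if table.shape[0] < 2:
                logger.warning(
                    "chisq_clinical: cluster %r membership constant for %r; skipped",
                    cluster, var,
                )
                continue
            stat, p, dof, expected = chi2_contingency(
                table.to_numpy(), correction=continuity
            )
            low = bool((expected < 5).any())
            if low:
                logger.warning(
                    "chisq_clinical: expected count < 5 in (%r, %r) table", cluster, var
                )
            rows.append(
                {
                    "cluster": cluster,
                    "variable": var,
                    "statistic": float(stat),
                    "df": int(dof),
                    "p_raw": float(p),
                    "n": int(table.to_numpy().sum()),
                    "low_expected": low,
                }
            )
    out = pd.DataFrame(rows)
    if len(out) and correction == "bonferroni":
        out["p_adj"] = np.minimum(out["p_raw"] * len(out), 1.0)
    elif len(out):
        out["p_adj"] = out["p_raw"]
    return out
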