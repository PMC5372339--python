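"""Cluster-of-clusters (COCA) integration of per-layer classifications.

The per-layer categorical labels are one-hot encoded into a binary
membership matrix (samples x (layer, cluster) indicators with a per-layer
observed mask), compared with a missingness-normalized Manhattan distance,
and integrated by resampling-based consensus clustering (Ward linkage).
The number of integrated clusters is chosen by the average silhouette
width, with the consensus-CDF area curves reported as the supporting
criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationLayer",
    "MembershipMatrix",
    "ConsensusResult",
    "build_membership",
    "normalized_manhattan",
    "consensus_cluster",
    "silhouette_widths",
]


@dataclass
class ClassificationLayer:
    """One named layer's categorical label per sample; NaN marks missing."""

    name: str
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            dups = self.labels.index[self.labels.index.duplicated()].unique()
            raise ValueError(f"layer {self.name!r} has duplicate sample ids: {list(dups)}")
        self.labels = self.labels.rename(self.name)

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self.labels.dropna().astype(str).unique())


@dataclass
class MembershipMatrix:
    """One-hot layer membership: samples x (layer, cluster) indicators.

    ``indicators`` has a two-level column index (layer, cluster) with values
    in {0, 1}; ``observed`` is samples x layers boolean. Within an observed
    (sample, layer) exactly one indicator is 1; unobserved layers have all
    indicators 0 but are excluded from distances via the mask.
    """

    indicators: pd.DataFrame
    observed: pd.DataFrame
    dropped: list = field(default_factory=list)

    @property
    def samples(self) -> pd.Index:
        return self.indicators.index

    @property
    def layers(self) -> list[str]:
        return list(self.observed.columns)


def build_membership(
    layers: list[ClassificationLayer], min_layers: int = 2
) -> MembershipMatrix:
    """One-hot encode layer labels, dropping samples seen in too few layers.

    Samples observed in fewer than ``min_layers`` layers are excluded and
    listed in the result's ``dropped`` report (mirrors the at-least-two-levels
    inclusion rule of the integrated analysis).
    """
    if len(layers) < 2:
        raise ValueError("at least two classification layers are required")
    names = [l.name for l in layers]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate layer names: {names}")

    all_samples = pd.Index([])
    for layer in layers:
        all_samples = all_samples.union(layer.labels.index)

    observed = pd.DataFrame(False, index=all_samples, columns=names)
    for layer in layers:
        obs = layer.labels.dropna().index
        observed.loc[obs, layer.name] = True

    n_obs = observed.sum(axis=1)
    keep = n_obs >= min_layers
    dropped = list(all_samples[~keep])
    if dropped:
        logger.info(
            "build_membership: dropped %d samples observed in < %d layers",
            len(dropped), min_layers,
        )
    kept = all_samples[keep]

    blocks = []
    for layer in layers:
        lab = layer.labels.reindex(kept).astype(object)
        dummies = pd.get_dummies(lab, dtype=int)
        dummies = dummies.reindex(columns=layer.vocabulary, fill_value=0)
        dummies.columns = pd.MultiIndex.from_product(
            [[layer.name], dummies.columns], names=["layer", "cluster"]
        )
        blocks.append(dummies)
    indicators = pd.concat(blocks, axis=1)
    return MembershipMatrix(indicators, observed.loc[kept], dropped)


def normalized_manhattan(m: MembershipMatrix) -> pd.DataFrame:
    """Missingness-normalized Manhattan distance between membership rows.

    d(i, j) averages, over the layers observed in both samples, the Manhattan
    distance between the one-hot blocks — i.e. d = 2 x (fraction of shared
    layers on which the two samples disagree), so d is in [0, 2] and layers
    with many missing values are not down-weighted relative to complete ones.
    Pairs sharing no observed layer get the maximal distance 2 with a warning.
    """
    samples = m.samples
    n = len(samples)
    obs = m.observed.to_numpy(dtype=bool)  # n x L

    # integer label codes per layer; -1 where unobserved
    codes = np.full((n, len(m.layers)), -1, dtype=int)
    layer_cols = set(m.indicators.columns.get_level_values(0))
    for li, layer in enumerate(m.layers):
        if layer not in layer_cols:  # no observed label anywhere
            continue
        block = m.indicators[layer].to_numpy()
        has = obs[:, li]
        codes[has, li] = block[has].argmax(axis=1)

    shared = obs[:, None, :] & obs[None, :, :]  # n x n x L
    disagree = (codes[:, None, :] != codes[None, :, :]) & shared
    n_shared = shared.sum(axis=2)
    n_disagree = disagree.sum(axis=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        d = 2.0 * n_disagree / n_shared
    empty = n_shared == 0
    if empty.any():
        n_pairs = (empty.sum() - np.diag(empty).sum()) // 2
        if n_pairs > 0:
            logger.warning(
                "normalized_manhattan: %d sample pairs share no observed layer; "
                "distance set to 2", int(n_pairs),
            )
    d[empty] = 2.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=samples, columns=samples)


def silhouette_widths(
    labels: pd.Series | np.ndarray, dist: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths on a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    the sample's own cluster (excluding itself) and b(i) the smallest mean
    distance to any other cluster; members of singleton clusters get s = 0.
    """
    lab = np.asarray(labels)
    d = np.asarray(dist, dtype=float)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    n = len(lab)
    s = np.zeros(n)
    masks = {c: lab == c for c in uniq}
    sizes = {c: masks[c].sum() for c in uniq}
    for i in range(n):
        own = lab[i]
        if sizes[own] == 1:
            s[i] = 0.0
            continue
        a = d[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(d[i, masks[c]].mean() for c in uniq if c != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


@dataclass
class ConsensusResult:
    """Outcome of resampled consensus clustering over a K range."""

    k_range: list[int]
    consensus: dict[int, pd.DataFrame]
    labels: dict[int, pd.Series]
    silhouette: dict[int, float]  # on the normalized Manhattan distance
    silhouette_consensus: dict[int, float]  # on 1 - consensus
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    reps: int
    subsample_frac: float
    seed: int
    select_by: str = "distance"

    @property
    def chosen_labels(self) -> pd.Series:
        return self.labels[self.chosen_k]


def _consensus_cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = np.sort(consensus[iu])
    n = len(vals)
    if n == 0:
        return 0.0
    # CDF evaluated on a [0, 1] grid of the observed values
    grid = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.concatenate([[0.0], (np.arange(n) + 1) / n, [1.0]])
    return float(np.trapezoid(cdf, grid))


def consensus_cluster(
    m: MembershipMatrix,
    k_range: range | list[int] = range(2, 11),
    reps: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    select_by: str = "distance",
) -> ConsensusResult:
    """Resampled consensus clustering of the membership matrix.

    For each repetition, a subsample of ceil(frac * n) samples is drawn
    without replacement and Ward-clustered on the normalized Manhattan
    distance at every K; consensus(i, j) is the fraction of co-samplings in
    which i and j co-clustered. Final labels per K come from Ward clustering
    of 1 - consensus. The average silhouette of the final grouping is
    computed both on the normalized Manhattan distance (the default
    selection criterion) and on 1 - consensus (the grouping's stability);
    K is the argmax of the ``select_by`` silhouette, with the CDF/delta-area
    curves reported as the supporting criterion.
    """
    if select_by not in ("consensus", "distance"):
        raise ValueError(f"unknown select_by {select_by!r}")
    ks = sorted(k_range)
    n = len(m.samples)
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")

    rng = np.random.default_rng(seed)
    dist = normalized_manhattan(m)
    dmat = dist.to_numpy()
    n_sub = int(np.ceil(subsample_frac * n))

    together = {k: np.zeros((n, n)) for k in ks}
    co_sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1.0
        sub = dmat[np.ix_(idx, idx)]
        z = linkage(squareform(sub, checks=False), method="ward")
        for k in ks:
            lab = fcluster(z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            together[k][np.ix_(idx, idx)] += same

    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        logger.warning(
            "consensus_cluster: %d sample pairs never co-sampled; consensus set to 0",
            int(never.sum() // 2),
        )
    denom = np.where(co_sampled == 0, 1.0, co_sampled)

    consensus, labels, sil, sil_cons, areas = {}, {}, {}, {}, {}
    for k in ks:
        c = together[k] / denom
        c[never] = 0.0
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
        consensus[k] = pd.DataFrame(c, index=m.samples, columns=m.samples)
        cdist = 1.0 - c
        np.fill_diagonal(cdist, 0.0)
        z = linkage(squareform(cdist, checks=False), method="ward")
        lab = fcluster(z, t=k, criterion="maxclust")
        labels[k] = pd.Series(lab, index=m.samples, name=f"coca_k{k}")
        _, sil[k] = silhouette_widths(lab, dmat)
        _, sil_cons[k] = silhouette_widths(lab, cdist)
        areas[k] = _consensus_cdf_area(c)

    delta = {}
    prev = None
    for k in ks:
        delta[k] = areas[k] if prev is None else (areas[k] - prev) / prev
        prev = areas[k]

    criterion = sil_cons if select_by == "consensus" else sil
    chosen = max(ks, key=lambda k: criterion[k])
    return ConsensusResult(
        k_range=ks,
        consensus=consensus,
        labels=labels,
        silhouette=sil,
        silhouette_consensus=sil_cons,
        cdf_area=areas,
        delta_area=delta,
        chosen_k=chosen,
        reps=reps,
        subsample_frac=subsample_frac,
        seed=seed,
        select_by=select_by,
    )
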