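"""Single-layer tumor classifiers feeding the cluster-of-clusters integration.

Each classifier in this module turns one molecular data level into a
categorical per-sample label: correlation-based centroid subtyping of mRNA
expression (with cohort re-centering against a training reference), nearest
shrunken centroid (NSC) assignment to fixed integrative-cluster centroids,
grouping by the number of chromosome arms with a complex copy-number
aberration, recursive gap-statistic partitioning (PART) of miRNA profiles,
and preprocessing plus hierarchical clustering of metabolic spectra.

Expression matrices are plain :class:`pandas.DataFrame` objects with
features on the rows and samples on the columns, values on log2 scale and
``NaN`` marking missing entries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "CentroidModel",
    "NSCModel",
    "CAAIProfile",
    "PartConfig",
    "SpectrumSet",
    "combined_centroid",
    "centroid_assign",
    "normalize_to_reference",
    "nsc_shrink",
    "nsc_assign",
    "caai_group",
    "gap_statistic",
    "part_cluster",
    "preprocess_spectra",
    "hcluster_cut",
    "pairwise_distance",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CentroidModel:
    """Reference centroids for correlation-based subtype assignment.

    Parameters
    ----------
    centroids
        Genes x subtypes table of reference centroid values.
    training_centroid
        Per-gene centroid of the original training cohort, used to re-center
        a new cohort onto the training scale.
    er_neg_proportion
        Proportion ``c`` of ER-negative samples in the training cohort; the
        cohort's combined centroid is ``c * mean(ER-) + (1 - c) * mean(ER+)``.
    """

    centroids: pd.DataFrame
    training_centroid: pd.Series
    er_neg_proportion: float

    def __post_init__(self) -> None:
        if not 0.0 < self.er_neg_proportion < 1.0:
            raise ValueError(
                f"er_neg_proportion must be in (0, 1), got {self.er_neg_proportion}"
            )
        if not self.centroids.index.equals(self.training_centroid.index):
            self.training_centroid = self.training_centroid.reindex(self.centroids.index)
            if self.training_centroid.isna().any():
                raise ValueError("training_centroid does not cover the model gene list")

    @property
    def genes(self) -> pd.Index:
        return self.centroids.index

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)


@dataclass
class NSCModel:
    """Nearest-shrunken-centroid model on fixed reference centroids.

    Attributes mirror the classical NSC parameterisation: per-class centroids
    ``x_bar_k``, overall centroid ``x_bar``, pooled within-class standard
    deviation ``s_j``, fudge constant ``s0`` guarding against tiny variances,
    class-size factors ``m_k``, soft-threshold amount ``delta`` and class
    priors ``pi_k``.
    """

    centroids: pd.DataFrame  # features x classes
    overall_centroid: pd.Series  # per feature
    s: pd.Series  # pooled within-class sd per feature
    s0: float
    m: pd.Series  # per class
    delta: float = 0.0
    priors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.s < 0).any():
            raise ValueError("pooled within-class sd must be non-negative")
        if self.delta < 0:
            raise ValueError("shrinkage threshold delta must be >= 0")
        if self.priors is None:
            k = self.centroids.shape[1]
            self.priors = pd.Series(1.0 / k, index=self.centroids.columns)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")

    @property
    def classes(self) -> list[str]:
        return list(self.centroids.columns)


@dataclass
class CAAIProfile:
    """Per-chromosome-arm complex arm aberration index scores for one sample."""

    scores: pd.Series  # arm -> score, NaN = missing
    tau: float = 0.5

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        finite = self.scores.dropna()
        if not np.isfinite(finite.to_numpy(dtype=float)).all():
            raise ValueError("CAAI scores must be finite where present")


@dataclass
class PartConfig:
    """Settings for recursive gap-statistic partitioning.

    ``kmax`` caps the children tried per node, ``min_size`` is the smallest
    admissible cluster, ``b`` the number of uniform reference datasets for
    the gap statistic.
    """

    kmax: int = 4
    min_size: int = 41
    b: int = 1000
    distance: str = "pearson"
    linkage: str = "complete"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if self.distance not in ("pearson", "euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.linkage not in ("complete", "ward", "average"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


@dataclass
class SpectrumSet:
    """HR MAS MR spectra: a ppm axis plus a samples x bins intensity matrix."""

    ppm: np.ndarray
    intensities: pd.DataFrame  # samples x ppm bins
    include_window: tuple[float, float] = (1.40, 4.70)
    exclude_windows: list[tuple[float, float]] = field(
        default_factory=lambda: [
            (4.27, 4.36),
            (2.70, 2.88),
            (2.20, 2.30),
            (1.93, 2.09),
            (1.50, 1.67),
        ]
    )

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.shape[0] != self.intensities.shape[1]:
            raise ValueError("ppm axis length must match intensity columns")
        lo, hi = sorted(self.include_window)
        self.include_window = (lo, hi)
        self.exclude_windows = [tuple(sorted(w)) for w in self.exclude_windows]
        for a, b in self.exclude_windows:
            if a < lo or b > hi:
                raise ValueError(f"exclusion window ({a}, {b}) outside inclusion window")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")


# ---------------------------------------------------------------------------
# centroid subtyping
# ---------------------------------------------------------------------------


def combined_centroid(
    expr: pd.DataFrame, er_status: pd.Series, model: CentroidModel
) -> pd.Series:
    """ER-proportion-weighted average of the cohort's ER- and ER+ mean vectors.

    The returned per-gene vector is ``c * mean(ER-) + (1 - c) * mean(ER+)``
    with ``c`` the training cohort's ER-negative proportion; subtracting it
    from each sample and adding the training centroid aligns a new cohort to
    the training reference before centroid correlation.

    Raises
    ------
    ValueError
        If either ER class has no sample with known status; the caller must
        then skip re-centering explicitly.
    """
    er = er_status.reindex(expr.columns).dropna()
    neg = er[er == "neg"].index
    pos = er[er == "pos"].index
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError(
            "combined centroid needs at least one ER-positive and one ER-negative "
            "sample with known status; skip re-centering explicitly if unavailable"
        )
    c = model.er_neg_proportion
    genes = expr.index.intersection(model.genes)
    mean_neg = expr.loc[genes, neg].mean(axis=1)
    mean_pos = expr.loc[genes, pos].mean(axis=1)
    return c * mean_neg + (1.0 - c) * mean_pos


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties; NaN if either side constant."""
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def centroid_assign(
    expr: pd.DataFrame,
    er_status: pd.Series,
    model: CentroidModel,
    min_coverage: float = 0.9,
) -> pd.DataFrame:
    """Assign each sample to the best-correlated reference centroid.

    Each sample vector is centered as ``x - combined_centroid +
    training_centroid`` and then Spearman-correlated with every reference
    centroid on the shared genes; the label is the centroid with the largest
    correlation. Samples whose centered vector is constant (undefined ranks)
    are labeled ``"unassigned"``.

    Returns a DataFrame indexed by sample with a ``label`` column and one
    correlation column per subtype.
    """
    shared = expr.index.intersection(model.genes)
    coverage = len(shared) / len(model.genes)
    if coverage < min_coverage:
        raise ValueError(
            f"expression covers only {len(shared)}/{len(model.genes)} model genes "
            f"({coverage:.0%} < required {min_coverage:.0%})"
        )
    sub = expr.loc[shared]
    combined = combined_centroid(sub, er_status, model)
    centered = sub.sub(combined, axis=0).add(model.training_centroid.loc[shared], axis=0)

    cent = model.centroids.loc[shared]
    rows = []
    for sample in centered.columns:
        x = centered[sample].to_numpy(dtype=float)
        cors = {k: _spearman(x, cent[k].to_numpy(dtype=float)) for k in model.subtypes}
        series = pd.Series(cors)
        if series.isna().all():
            label = "unassigned"
        else:
            label = series.idxmax()
        rows.append({"sample": sample, "label": label, **cors})
    out = pd.DataFrame(rows).set_index("sample")
    return out


def normalize_to_reference(
    expr: pd.DataFrame, ref_mean: pd.Series, ref_sd: pd.Series
) -> pd.DataFrame:
    """Rescale each feature to a reference mean and standard deviation.

    Features are z-scored against the cohort's own mean/sd, then scaled by
    ``ref_sd`` and shifted by ``ref_mean``. A feature that is constant in the
    cohort is set to its reference mean with a logged warning.
    """
    ref_mean = ref_mean.reindex(expr.index)
    ref_sd = ref_sd.reindex(expr.index)
    if (ref_sd <= 0).any():
        bad = list(ref_sd.index[ref_sd <= 0])
        raise ValueError(f"reference sd must be positive, offending features: {bad}")
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "normalize_to_reference: %d constant features set to reference mean",
            int(constant.sum()),
        )
    sd_safe = sd.mask(constant, 1.0)
    z = expr.sub(mu, axis=0).div(sd_safe, axis=0)
    out = z.mul(ref_sd, axis=0).add(ref_mean, axis=0)
    out.loc[constant] = np.broadcast_to(
        ref_mean[constant].to_numpy()[:, None], out.loc[constant].shape
    )
    return out


# ---------------------------------------------------------------------------
# nearest shrunken centroid
# ---------------------------------------------------------------------------


def nsc_shrink(model: NSCModel) -> pd.DataFrame:
    """Soft-threshold class centroids toward the overall centroid.

    Standardized differences d_kj = (x_bar_kj - x_bar_j) / (m_k (s_j + s0))
    are shrunk by ``delta`` (soft thresholding toward zero) and mapped back:
    x'_kj = x_bar_j + m_k (s_j + s0) d'_kj. With delta = 0 the original
    centroids are returned unchanged.
    """
    denom_feat = model.s + model.s0
    shrunken = {}
    for k in model.classes:
        d = (model.centroids[k] - model.overall_centroid) / (model.m[k] * denom_feat)
        d_shr = np.sign(d) * np.maximum(d.abs() - model.delta, 0.0)
        shrunken[k] = model.overall_centroid + model.m[k] * denom_feat * d_shr
    return pd.DataFrame(shrunken)[model.classes]


def nsc_assign(expr: pd.DataFrame, model: NSCModel) -> pd.DataFrame:
    """Assign samples to the nearest shrunken centroid by discriminant score.

    delta_k(x) = sum_j (x_j - x'_kj)^2 / (s_j + s0)^2 - 2 log pi_k; the label
    is the argmin over classes, ties broken toward the lowest class index and
    flagged in the ``tie`` column.
    """
    missing = model.centroids.index.difference(expr.index)
    if len(missing) > 0:
        raise ValueError(f"expression matrix lacks model features: {list(missing)}")
    sub = expr.loc[model.centroids.index]
    shrunk = nsc_shrink(model)
    denom = (model.s + model.s0).to_numpy() ** 2

    x = sub.to_numpy(dtype=float)  # features x samples
    scores = {}
    for k in model.classes:
        diff = x - shrunk[k].to_numpy()[:, None]
        scores[k] = (diff**2 / denom[:, None]).sum(axis=0) - 2.0 * np.log(
            model.priors[k]
        )
    score_df = pd.DataFrame(scores, index=sub.columns)
    arr = score_df.to_numpy()
    best = arr.argmin(axis=1)
    ties = (np.isclose(arr, arr.min(axis=1, keepdims=True))).sum(axis=1) > 1
    out = score_df.copy()
    out.insert(0, "label", [model.classes[i] for i in best])
    out["tie"] = ties
    return out


# ---------------------------------------------------------------------------
# CAAI grouping
# ---------------------------------------------------------------------------


def caai_group(profile: CAAIProfile) -> str | None:
    """Label a sample by its count of complex-aberration arms: "0", "1" or "2".

    An arm counts as an event when its score is >= tau (default 0.5); two or
    more events collapse into the "2" group. Returns ``None`` when every arm
    score is missing.
    """
    present = profile.scores.dropna()
    if len(present) == 0:
        return None
    n_events = int((present >= profile.tau).sum())
    return str(min(n_events, 2))


# ---------------------------------------------------------------------------
# distances + hierarchical clustering
# ---------------------------------------------------------------------------


def pairwise_distance(data: np.ndarray, distance: str) -> np.ndarray:
    """Condensed pairwise distances between rows: euclidean or 1 - Pearson r."""
    if distance == "euclidean":
        return pdist(data, metric="euclidean")
    if distance == "pearson":
        d = pdist(data, metric="correlation")
        # pdist's correlation distance is exactly 1 - r; clip fp noise
        return np.clip(d, 0.0, 2.0)
    raise ValueError(f"unknown distance {distance!r}")


def hcluster_cut(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    method: str = "ward",
    k: int = 2,
) -> pd.Series:
    """Agglomerative clustering of samples, dendrogram cut into exactly k groups.

    ``matrix`` is features x samples; samples (columns) are clustered.
    Pearson distance is 1 - r between sample profiles. Ward on non-Euclidean
    distances follows the standard Lance-Williams update.
    """
    n = matrix.shape[1]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    data = matrix.to_numpy(dtype=float).T
    condensed = pairwise_distance(data, distance)
    z = linkage(condensed, method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.columns, name="cluster")


# ---------------------------------------------------------------------------
# gap statistic + PART
# ---------------------------------------------------------------------------


def _within_dispersion(condensed: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (sum of pairwise distances) / (2 n_r)."""
    d = squareform(condensed)
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * len(idx))
    return total


def _cut_tree(condensed: np.ndarray, method: str, k: int, n: int) -> np.ndarray:
    if k == 1:
        return np.zeros(n, dtype=int)
    z = linkage(condensed, method=method)
    return fcluster(z, t=k, criterion="maxclust")


def gap_statistic(
    data: np.ndarray,
    distance: str = "euclidean",
    method: str = "ward",
    k_range: range | list[int] = range(1, 5),
    b: int = 50,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Tibshirani-style gap statistic under flat dendrogram cuts.

    For each k, gap(k) = mean_b log W_k(ref_b) - log W_k(data) with W_k the
    within-cluster dispersion of the k-cut, references drawn uniformly per
    feature over the observed range, and se(k) = sd_b(log W_k(ref)) *
    sqrt(1 + 1/B). Constant data yields a degenerate result recommending k=1.

    Returns a DataFrame indexed by k with columns ``gap``, ``se``,
    ``log_w``, ``log_w_ref`` and an attribute-style column ``selected``
    marking the chosen k (first k with gap(k) >= gap(k+1) - se(k+1)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    ks = sorted(k_range)
    if any(k < 1 or k > max(n - 1, 1) for k in ks):
        raise ValueError(f"k_range must lie within [1, {n - 1}]")

    condensed = pairwise_distance(data, distance)
    if np.allclose(condensed, 0.0):
        out = pd.DataFrame(
            {"gap": np.nan, "se": np.nan, "log_w": np.nan, "log_w_ref": np.nan,
             "selected": False},
            index=pd.Index(ks, name="k"),
        )
        out.attrs["selected_k"] = 1
        return out

    lo = data.min(axis=0)
    hi = data.max(axis=0)
    span = hi - lo

    log_w = np.full(len(ks), np.nan)
    for i, k in enumerate(ks):
        labels = _cut_tree(condensed, method, k, n)
        w = _within_dispersion(condensed, labels)
        log_w[i] = np.log(w) if w > 0 else -np.inf

    ref_log_w = np.full((b, len(ks)), np.nan)
    for bi in range(b):
        ref = lo + rng.random(data.shape) * span
        ref_cond = pairwise_distance(ref, distance)
        for i, k in enumerate(ks):
            labels = _cut_tree(ref_cond, method, k, n)
            w = _within_dispersion(ref_cond, labels)
            ref_log_w[bi, i] = np.log(w) if w > 0 else -np.inf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_ref = ref_log_w.mean(axis=0)
        gap = mean_ref - log_w
        se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / b)

    selected_k = ks[-1]
    for i in range(len(ks) - 1):
        if not np.isfinite(gap[i]):
            selected_k = ks[i]
            break
        if gap[i] >= gap[i + 1] - se[i + 1]:
            selected_k = ks[i]
            break

    out = pd.DataFrame(
        {"gap": gap, "se": se, "log_w": log_w, "log_w_ref": mean_ref},
        index=pd.Index(ks, name="k"),
    )
    out["selected"] = out.index == selected_k
    out.attrs["selected_k"] = selected_k
    return out


def part_cluster(expr: pd.DataFrame, config: PartConfig) -> pd.Series:
    """Recursive partitioning of samples with clusters at different heights.

    At each node the node's samples are clustered hierarchically and a flat
    cut at the gap-selected k (1..kmax) is attempted; a node becomes a leaf
    when the gap criterion selects k=1 or a resulting child would fall below
    ``min_size``. Leaves are numbered 1.. in discovery (depth-first) order.

    ``expr`` is features x samples; the returned Series maps sample to leaf.
    """
    samples = list(expr.columns)
    data = expr.to_numpy(dtype=float).T
    rng = np.random.default_rng(config.seed)
    labels = pd.Series(0, index=expr.columns, name="cluster", dtype=int)
    next_leaf = [0]

    def make_leaf(idx: np.ndarray) -> None:
        next_leaf[0] += 1
        labels.iloc[idx] = next_leaf[0]

    def recurse(idx: np.ndarray) -> None:
        node = data[idx]
        if len(idx) <= 2 * config.min_size:
            make_leaf(idx)
            return
        ks = range(1, config.kmax + 1)
        gaps = gap_statistic(
            node, config.distance, config.linkage, ks, b=config.b, seed=rng
        )
        k = gaps.attrs["selected_k"]
        if k == 1:
            make_leaf(idx)
            return
        condensed = pairwise_distance(node, config.distance)
        child_labels = _cut_tree(condensed, config.linkage, k, len(idx))
        sizes = np.bincount(child_labels)[1:]
        if (sizes < config.min_size).any():
            make_leaf(idx)
            return
        for lab in np.unique(child_labels):
            recurse(idx[child_labels == lab])

    recurse(np.arange(len(samples)))
    return labels


# ---------------------------------------------------------------------------
# metabolic spectra
# ---------------------------------------------------------------------------


def preprocess_spectra(spectra: SpectrumSet) -> pd.DataFrame:
    """Window, exclude lipid regions, and mean-normalize MR spectra.

    Bins inside the inclusion window but outside every exclusion window are
    retained; each sample's retained vector is divided by its own mean, so
    every sample averages to 1. Returns a features (ppm bins) x samples
    matrix with bins named ``ppm_<value>``.
    """
    ppm = spectra.ppm
    lo, hi = spectra.include_window
    keep = (ppm >= lo) & (ppm <= hi)
    for a, b in spectra.exclude_windows:
        keep &= ~((ppm >= a) & (ppm <= b))
    if not keep.any():
        raise ValueError("no ppm bins retained after windowing")
    retained = spectra.intensities.loc[:, keep]
    means = retained.mean(axis=1)
    if (means == 0).any():
        raise ValueError("sample with zero mean intensity in retained region")
    normed = retained.div(means, axis=0)
    out = normed.T
    out.index = [f"ppm_{p:.4f}" for p in ppm[keep]]
    return out
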