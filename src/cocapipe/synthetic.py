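"""Synthetic multi-level breast-tumor cohorts for end-to-end testing.

The generator emulates the statistical structure the integrated analysis
assumes: a latent six-group cohort (five subtype-like groups plus a split of
the largest, luminal-A-like group that is visible only in the miRNA layer),
seven categorical classification layers observed with per-layer label noise
(confusion matrices) and missingness, subtype-structured log2 expression
matrices carrying a planted split signature, per-arm copy-number complexity
scores consistent with the drawn complexity grouping, and group-dependent
exponential survival.

All randomness flows from a single integer seed that fans out to fixed
per-component child streams, so identical specs produce byte-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .integration import ClassificationLayer

__all__ = [
    "LayerSpec",
    "ExpressionSpec",
    "SplitSpec",
    "SurvivalSpec",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_survival",
    "default_cohort_spec",
]


class SpecValidationError(ValueError):
    """A cohort spec violated an invariant; the message names the field."""


@dataclass
class LayerSpec:
    """One classification layer: cluster vocabulary, confusion and missingness.

    ``confusion`` is a latent-group x layer-cluster row-stochastic matrix:
    row g gives the label distribution for samples of latent group g.
    """

    name: str
    clusters: list[str]
    confusion: pd.DataFrame
    missing_rate: float = 0.0


@dataclass
class ExpressionSpec:
    """A subtype-structured log2 expression matrix.

    Each latent group gets ``markers_per_group`` marker features shifted by
    ``shift`` log2 units in that group's samples — except that the two
    halves of a planted split share one marker block, so the halves differ
    in expression only through the split signature. Everything else is
    i.i.d. Gaussian noise on log2 scale. When ``carries_signature`` is set,
    the cohort's split-signature features are appended to this matrix;
    ``coupled_genes`` adds features linearly coupled to the signature (for
    correlation-filter testing).
    """

    name: str
    n_features: int = 180
    markers_per_group: int = 20
    shift: float = 1.2
    noise_sd: float = 0.5
    carries_signature: bool = False
    coupled_genes: int = 0
    coupling: float = 0.8


@dataclass
class SplitSpec:
    """The planted split: two halves of one subtype differing only in the
    driving layer's labels, a signature-feature mean shift, and hazard."""

    group_a: str
    group_b: str
    driving_layer: str
    n_signature_features: int = 71
    effect_size: float = 1.5


@dataclass
class SurvivalSpec:
    """Per-group exponential event hazards and an independent censoring rate.

    ``censoring_rate`` is the expected censored fraction: censoring times
    are exponential with hazard h_g * r / (1 - r), which under exponential
    event times censors exactly a fraction r in expectation.
    """

    hazards: dict[str, float]
    censoring_rate: float = 0.3


@dataclass
class CohortSpec:
    """Full recipe for a synthetic cohort; validated before generation."""

    n_samples: int
    latent_groups: list[tuple[str, float]]
    layers: list[LayerSpec]
    split: SplitSpec | None = None
    expression: list[ExpressionSpec] = field(default_factory=list)
    survival: SurvivalSpec | None = None
    caai_layer: str | None = None
    n_arms: int = 39
    seed: int = 0

    def validate(self) -> None:
        names = [g for g, _ in self.latent_groups]
        props = np.array([p for _, p in self.latent_groups], dtype=float)
        if self.n_samples < 1:
            raise SpecValidationError("n_samples must be >= 1")
        if len(set(names)) != len(names):
            raise SpecValidationError("latent_groups: duplicate group names")
        if not np.isclose(props.sum(), 1.0):
            raise SpecValidationError(
                f"latent_groups: proportions sum to {props.sum():.6f}, expected 1"
            )
        if (props <= 0).any():
            raise SpecValidationError("latent_groups: proportions must be positive")
        layer_names = [l.name for l in self.layers]
        if len(set(layer_names)) != len(layer_names):
            raise SpecValidationError("layers: duplicate layer names")
        for layer in self.layers:
            if not 0 <= layer.missing_rate < 1:
                raise SpecValidationError(
                    f"layers[{layer.name}].missing_rate must be in [0, 1)"
                )
            conf = layer.confusion
            if list(conf.columns) != list(layer.clusters):
                raise SpecValidationError(
                    f"layers[{layer.name}].confusion columns must equal clusters"
                )
            if set(conf.index) != set(names):
                raise SpecValidationError(
                    f"layers[{layer.name}].confusion rows must cover latent groups"
                )
            rows = conf.to_numpy(dtype=float)
            if (rows < 0).any() or not np.allclose(rows.sum(axis=1), 1.0):
                raise SpecValidationError(
                    f"layers[{layer.name}].confusion rows must be non-negative and sum to 1"
                )
        if self.split is not None:
            s = self.split
            for g in (s.group_a, s.group_b):
                if g not in names:
                    raise SpecValidationError(f"split: unknown latent group {g!r}")
            if s.driving_layer not in layer_names:
                raise SpecValidationError(f"split.driving_layer {s.driving_layer!r} unknown")
            if s.n_signature_features < 1:
                raise SpecValidationError("split.n_signature_features must be >= 1")
            for layer in self.layers:
                if layer.name == s.driving_layer:
                    continue
                ra = layer.confusion.loc[s.group_a]
                rb = layer.confusion.loc[s.group_b]
                if not np.allclose(ra.to_numpy(float), rb.to_numpy(float)):
                    raise SpecValidationError(
                        f"layers[{layer.name}]: split halves must have identical "
                        "confusion rows outside the driving layer"
                    )
        for es in self.expression:
            if es.noise_sd <= 0:
                raise SpecValidationError(f"expression[{es.name}].noise_sd must be > 0")
            if es.markers_per_group < 0 or es.n_features < 0:
                raise SpecValidationError(
                    f"expression[{es.name}]: feature counts must be non-negative"
                )
        if self.split is not None and self.expression:
            if not any(es.carries_signature for es in self.expression):
                raise SpecValidationError(
                    "split requires one expression spec with carries_signature=True"
                )
        if self.survival is not None:
            missing = set(names) - set(self.survival.hazards)
            if missing:
                raise SpecValidationError(f"survival.hazards missing groups: {sorted(missing)}")
            if any(h <= 0 for h in self.survival.hazards.values()):
                raise SpecValidationError("survival.hazards must be positive")
            if not 0 <= self.survival.censoring_rate < 1:
                raise SpecValidationError("survival.censoring_rate must be in [0, 1)")
        if self.caai_layer is not None and self.caai_layer not in layer_names:
            raise SpecValidationError(f"caai_layer {self.caai_layer!r} unknown")


@dataclass
class SyntheticCohort:
    """A generated cohort: latent truth plus everything the pipeline reads."""

    latent: pd.Series
    layers: dict[str, ClassificationLayer]
    drawn_labels: dict[str, pd.Series]  # layer labels before missingness masking
    expression: dict[str, pd.DataFrame]
    caai_scores: pd.DataFrame | None
    survival: pd.DataFrame | None
    signature_features: list[str]
    spec: CohortSpec


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-component stream from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _allocate_counts(n: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n samples to group proportions."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort from a validated spec; reproducible given the seed."""
    spec.validate()
    names = [g for g, _ in spec.latent_groups]
    props = np.array([p for _, p in spec.latent_groups], dtype=float)
    n = spec.n_samples

    counts = _allocate_counts(n, props)
    latent_arr = np.repeat(names, counts)
    rng0 = _child_rng(spec.seed, 0)
    latent_arr = latent_arr[rng0.permutation(n)]
    width = max(4, len(str(n)))
    sample_ids = pd.Index([f"S{i + 1:0{width}d}" for i in range(n)], name="sample")
    latent = pd.Series(latent_arr, index=sample_ids, name="latent")

    layers: dict[str, ClassificationLayer] = {}
    drawn: dict[str, pd.Series] = {}
    for li, layer in enumerate(spec.layers):
        rng = _child_rng(spec.seed, 1, li)
        conf = layer.confusion.loc[names, layer.clusters].to_numpy(dtype=float)
        gi = pd.Series(range(len(names)), index=names)[latent].to_numpy()
        # inverse-CDF draw per sample from its group's confusion row
        u = rng.random(n)
        cdf = conf.cumsum(axis=1)
        picks = (u[:, None] > cdf[gi]).sum(axis=1)
        labels = pd.Series(
            [layer.clusters[p] for p in picks], index=sample_ids, name=layer.name
        )
        drawn[layer.name] = labels
        observed = labels.astype(object)
        if layer.missing_rate > 0:
            mask = rng.random(n) < layer.missing_rate
            observed[mask] = np.nan
        layers[layer.name] = ClassificationLayer(layer.name, observed)

    # marker blocks are keyed by latent group, with the split halves sharing
    # one block so expression separates the halves only via the signature
    if spec.split is not None:
        merged = {spec.split.group_b: spec.split.group_a}
        block_groups = [g for g in names if g != spec.split.group_b]
    else:
        merged = {}
        block_groups = list(names)

    signature_features: list[str] = []
    expression: dict[str, pd.DataFrame] = {}
    sig_values: pd.DataFrame | None = None
    for ei, es in enumerate(spec.expression):
        rng = _child_rng(spec.seed, 2, ei)
        feats = [f"{es.name}-f{i + 1:04d}" for i in range(es.n_features)]
        x = rng.normal(0.0, es.noise_sd, size=(es.n_features, n))
        effective = latent.replace(merged)
        for bi, group in enumerate(block_groups):
            block = slice(bi * es.markers_per_group, (bi + 1) * es.markers_per_group)
            member = (effective == group).to_numpy()
            x[block, member] += es.shift
        mat = pd.DataFrame(x, index=feats, columns=sample_ids)

        if es.carries_signature and spec.split is not None:
            s = spec.split
            sig_names = [
                f"{es.name}-sig{i + 1:03d}" for i in range(s.n_signature_features)
            ]
            sig = rng.normal(0.0, es.noise_sd, size=(s.n_signature_features, n))
            # signed symmetric effects: the halves differ by effect_size per
            # feature, most features up in half A (mirrors real signatures,
            # and gives the split a correlation structure, not just a shift)
            signs = np.where(
                rng.random(s.n_signature_features) < 0.8, 1.0, -1.0
            )
            in_a = (latent == s.group_a).to_numpy()
            in_b = (latent == s.group_b).to_numpy()
            sig[:, in_a] += (signs * s.effect_size / 2.0)[:, None]
            sig[:, in_b] -= (signs * s.effect_size / 2.0)[:, None]
            sig_df = pd.DataFrame(sig, index=sig_names, columns=sample_ids)
            mat = pd.concat([mat, sig_df])
            signature_features = sig_names
            sig_values = sig_df

        if es.coupled_genes > 0:
            if sig_values is None:
                raise SpecValidationError(
                    f"expression[{es.name}].coupled_genes requires a preceding "
                    "signature-carrying expression spec"
                )
            src = sig_values.to_numpy()
            idx = rng.integers(0, src.shape[0], size=es.coupled_genes)
            coupled = es.coupling * src[idx] + rng.normal(
                0.0, es.noise_sd, size=(es.coupled_genes, n)
            )
            cnames = [f"{es.name}-cpl{i + 1:04d}" for i in range(es.coupled_genes)]
            mat = pd.concat(
                [mat, pd.DataFrame(coupled, index=cnames, columns=sample_ids)]
            )
        expression[es.name] = mat

    caai_scores = None
    if spec.caai_layer is not None:
        rng = _child_rng(spec.seed, 3)
        arms = [f"arm{i + 1:02d}" for i in range(spec.n_arms)]
        scores = rng.uniform(0.02, 0.45, size=(n, spec.n_arms))
        caai_labels = drawn[spec.caai_layer]
        for si in range(n):
            lab = caai_labels.iloc[si]
            n_high = {"0": 0, "1": 1}.get(str(lab), int(rng.integers(2, 5)))
            if n_high:
                hot = rng.choice(spec.n_arms, size=n_high, replace=False)
                scores[si, hot] = rng.uniform(0.55, 1.6, size=n_high)
        obs = layers[spec.caai_layer].labels
        scores[obs.isna().to_numpy(), :] = np.nan
        caai_scores = pd.DataFrame(scores, index=sample_ids, columns=arms)

    surv = None
    if spec.survival is not None:
        surv = generate_survival(
            latent, spec.survival, _child_rng(spec.seed, 4)
        )

    return SyntheticCohort(
        latent=latent,
        layers=layers,
        drawn_labels=drawn,
        expression=expression,
        caai_scores=caai_scores,
        survival=surv,
        signature_features=signature_features,
        spec=spec,
    )


def generate_survival(
    groups: pd.Series,
    spec: SurvivalSpec,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Exponential event times with group hazards and independent censoring.

    Returns a survival table with ``time``, ``event``, ``group``, a two-level
    ``hospital`` stratum and a binary ``radiation`` covariate (both drawn
    independently of outcome, for adjustment exercises).
    """
    unknown = set(groups.unique()) - set(spec.hazards)
    if unknown:
        raise SpecValidationError(f"generate_survival: unknown groups {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(groups)
    h = groups.map(spec.hazards).to_numpy(dtype=float)
    t_event = rng.exponential(1.0 / h)
    r = spec.censoring_rate
    if r > 0:
        h_cens = h * r / (1.0 - r)
        t_cens = rng.exponential(1.0 / h_cens)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "group": groups.to_numpy(),
            "hospital": rng.choice(["hospA", "hospB"], size=n),
            "radiation": rng.integers(0, 2, size=n),
        },
        index=groups.index,
    )


# ---------------------------------------------------------------------------
# default study-condition spec
# ---------------------------------------------------------------------------


def _conf(
    names: list[str],
    clusters: list[str],
    rows: dict[str, list[float]],
) -> pd.DataFrame:
    return pd.DataFrame([rows[g] for g in names], index=names, columns=clusters)


def _confident(clusters: list[str], target: str, eps: float) -> list[float]:
    m = len(clusters)
    row = [eps / (m - 1)] * m
    row[clusters.index(target)] = 1.0 - eps
    return row


def default_cohort_spec(seed: int = 0, n_samples: int = 420) -> CohortSpec:
    """The default six-group cohort the integrated analysis is tested on.

    Six latent groups: two luminal-A-like halves (75 + 82 of 420, split
    visible only in the miRNA layer), a luminal-B-like, basal-like,
    HER2-like and normal-like group. Seven classification layers mimic the
    relationships of the real levels: the mRNA-subtype and miRNA layers are
    confidently informative for all groups, the protein (RPPA), integrative
    (IntClust) and pathway (PARADIGM) layers are confident only for some
    groups and diffuse for the rest, and the copy-number-complexity and
    metabolic layers are weakly informative throughout — so the six groups
    sit at comparable pairwise separations rather than in a nested
    hierarchy. The miRNA expression matrix carries the 71-feature split
    signature at a 1.5 log2-unit effect; survival hazards give the split
    halves a hazard ratio of 2.5.
    """
    groups = ["lumA1", "lumA2", "lumB", "basal", "her2", "normal"]
    counts = np.array([75, 82, 106, 54, 50, 53], dtype=float)
    props = counts / counts.sum()

    pam = ["LumA", "LumB", "Basal", "Her2", "Normal"]
    mir = ["miR1", "miR2", "miR3", "miR4"]
    rppa = ["Luminal", "HER2", "Basal", "ReacI", "ReacII"]
    caai = ["0", "1", "2"]
    metab = ["M1", "M2", "M3"]
    ic = [f"IC{i}" for i in range(1, 11)]
    par = [f"P{i}" for i in range(1, 8)]

    reac_tilt = [0.15, 0.05, 0.02, 0.45, 0.33]  # shared by the two lumA halves

    def tilt(clusters: list[str], weights: dict[str, float]) -> list[float]:
        base = (1.0 - sum(weights.values())) / (len(clusters) - len(weights))
        return [weights.get(c, base) for c in clusters]

    layers = [
        LayerSpec(
            "pam50", pam,
            _conf(groups, pam, {
                "lumA1": _confident(pam, "LumA", 0.03),
                "lumA2": _confident(pam, "LumA", 0.03),
                "lumB": _confident(pam, "LumB", 0.03),
                "basal": _confident(pam, "Basal", 0.03),
                "her2": _confident(pam, "Her2", 0.03),
                "normal": _confident(pam, "Normal", 0.03),
            }),
            missing_rate=0.04,
        ),
        LayerSpec(
            "mirna", mir,
            _conf(groups, mir, {
                "lumA1": _confident(mir, "miR2", 0.015),
                "lumA2": _confident(mir, "miR1", 0.015),
                "lumB": _confident(mir, "miR1", 0.015),
                "basal": _confident(mir, "miR3", 0.015),
                "her2": _confident(mir, "miR2", 0.05),
                "normal": _confident(mir, "miR4", 0.015),
            }),
            missing_rate=0.005,
        ),
        LayerSpec(
            "rppa", rppa,
            _conf(groups, rppa, {
                "lumA1": reac_tilt,
                "lumA2": reac_tilt,
                "lumB": _confident(rppa, "Luminal", 0.15),
                "basal": _confident(rppa, "Basal", 0.08),
                "her2": _confident(rppa, "HER2", 0.08),
                "normal": _confident(rppa, "ReacII", 0.15),
            }),
            missing_rate=0.20,
        ),
        LayerSpec(
            "caai", caai,
            _conf(groups, caai, {
                "lumA1": [0.60, 0.25, 0.15],
                "lumA2": [0.60, 0.25, 0.15],
                "lumB": [0.40, 0.30, 0.30],
                "basal": [0.08, 0.27, 0.65],
                "her2": [0.12, 0.33, 0.55],
                "normal": [0.60, 0.25, 0.15],
            }),
            missing_rate=0.20,
        ),
        LayerSpec(
            "metabolic", metab,
            _conf(groups, metab, {
                "lumA1": [0.30, 0.45, 0.25],
                "lumA2": [0.30, 0.45, 0.25],
                "lumB": [0.45, 0.30, 0.25],
                "basal": [0.25, 0.25, 0.50],
                "her2": [0.30, 0.30, 0.40],
                "normal": [0.30, 0.45, 0.25],
            }),
            missing_rate=0.20,
        ),
        LayerSpec(
            "intclust", ic,
            _conf(groups, ic, {
                "lumA1": tilt(ic, {"IC3": 0.45, "IC4": 0.15, "IC8": 0.15}),
                "lumA2": tilt(ic, {"IC3": 0.45, "IC4": 0.15, "IC8": 0.15}),
                "lumB": tilt(ic, {"IC9": 0.40, "IC1": 0.15, "IC6": 0.15}),
                "basal": _confident(ic, "IC10", 0.08),
                "her2": _confident(ic, "IC5", 0.08),
                "normal": tilt(ic, {"IC4": 0.50, "IC3": 0.15}),
            }),
            missing_rate=0.20,
        ),
        LayerSpec(
            "paradigm", par,
            _conf(groups, par, {
                "lumA1": tilt(par, {"P3": 0.40, "P4": 0.30}),
                "lumA2": tilt(par, {"P3": 0.40, "P4": 0.30}),
                "lumB": _confident(par, "P1", 0.12),
                "basal": _confident(par, "P2", 0.08),
                "her2": tilt(par, {"P5": 0.45}),
                "normal": tilt(par, {"P6": 0.55}),
            }),
            missing_rate=0.20,
        ),
    ]

    expression = [
        ExpressionSpec(
            "mirna_expr", n_features=160, markers_per_group=25,
            shift=1.2, noise_sd=0.5, carries_signature=True,
        ),
        ExpressionSpec(
            "mrna_expr", n_features=200, markers_per_group=30,
            shift=1.0, noise_sd=0.5, coupled_genes=40,
        ),
        ExpressionSpec(
            "protein_expr", n_features=60, markers_per_group=10,
            shift=1.0, noise_sd=0.5,
        ),
    ]

    return CohortSpec(
        n_samples=n_samples,
        latent_groups=list(zip(groups, props)),
        layers=layers,
        split=SplitSpec("lumA1", "lumA2", "mirna", 71, 1.5),
        expression=expression,
        survival=SurvivalSpec(
            hazards={
                "lumA1": 0.04, "lumA2": 0.10, "lumB": 0.08,
                "basal": 0.12, "her2": 0.10, "normal": 0.05,
            },
            censoring_rate=0.3,
        ),
        caai_layer="caai",
        seed=seed,
    )
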