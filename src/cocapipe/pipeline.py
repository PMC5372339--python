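"""End-to-end orchestration: one reproducible run from config to report.

A run integrates classification layers into consensus clusters, ranks
layer-cluster associations, derives the signature discriminating a split
pair of clusters that share the same modal subtype, and validates the
signature against survival — writing every table as TSV into a run
directory together with a resolved config snapshot and its hash.

Inputs come either from delimited-text files or from the bundled synthetic
cohort generator; every stochastic stage is seeded from the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .association import membership_phi
from .integration import build_membership, consensus_cluster
from .signature import diffexp_two_group
from .survival import cox_hr, km_estimate, logrank_test, split_by_signature
from .synthetic import default_cohort_spec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (raised before any compute)."""


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    outdir: str
    seed: int = 0
    # input: either a synthetic cohort ...
    synthetic: bool = True
    n_samples: int = 420
    # ... or files
    layers_path: str | None = None
    expression_paths: dict[str, str] = field(default_factory=dict)
    survival_path: str | None = None
    # stage parameters
    min_layers: int = 2
    k_min: int = 2
    k_max: int = 10
    reps: int = 1000
    subsample_frac: float = 0.8
    select_by: str = "distance"
    na_policy: str = "zero"
    subtype_layer: str = "pam50"
    signature_expr: str = "mirna_expr"
    test: str = "wilcoxon"
    p_thresh: float = 0.01
    fc_thresh: float = 1.0
    run_signature: bool = True
    run_survival: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in d:
            raise ConfigError("config requires 'outdir'")
        return cls(**d)

    def validate(self) -> None:
        if not self.synthetic:
            if self.layers_path is None:
                raise ConfigError("non-synthetic run requires 'layers_path'")
            if not Path(self.layers_path).exists():
                raise ConfigError(f"layers_path does not exist: {self.layers_path}")
            for name, p in self.expression_paths.items():
                if not Path(p).exists():
                    raise ConfigError(f"expression path for {name!r} missing: {p}")
            if self.survival_path and not Path(self.survival_path).exists():
                raise ConfigError(f"survival_path does not exist: {self.survival_path}")
        if not 2 <= self.k_min <= self.k_max:
            raise ConfigError("need 2 <= k_min <= k_max")
        if self.reps < 2:
            raise ConfigError("reps must be >= 2")
        if not 0 < self.subsample_frac <= 1:
            raise ConfigError("subsample_frac must be in (0, 1]")
        if self.na_policy not in ("zero", "complete"):
            raise ConfigError(f"unknown na_policy {self.na_policy!r}")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _modal_split_pair(
    labels: pd.Series, subtype: pd.Series
) -> tuple[object, object, str] | None:
    """Find the two clusters sharing the same modal subtype label.

    Returns (cluster_a, cluster_b, shared_modal_label) for the largest such
    pair, or None when every cluster has a distinct modal subtype.
    """
    modal = {}
    for c in sorted(labels.unique(), key=str):
        sub = subtype.reindex(labels.index[labels == c]).dropna()
        if len(sub) == 0:
            continue
        modal[c] = sub.mode().iloc[0]
    by_label: dict[str, list] = {}
    for c, lab in modal.items():
        by_label.setdefault(lab, []).append(c)
    pairs = [
        (lab, cs) for lab, cs in by_label.items() if len(cs) >= 2
    ]
    if not pairs:
        return None
    # largest combined membership wins; within a >2-way tie take the two largest
    def pair_size(cs):
        return sum((labels == c).sum() for c in cs)

    lab, cs = max(pairs, key=lambda p: pair_size(p[1]))
    cs = sorted(cs, key=lambda c: -(labels == c).sum())[:2]
    return cs[0], cs[1], lab


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write the run directory.

    Returns a summary dict (chosen K, silhouettes, split pair, signature
    size, survival statistics) that mirrors ``summary.json`` in the output.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    summary: dict = {"config_hash": cfg_hash}
    files: list[str] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        files.append(name)

    # ---- stage: inputs -------------------------------------------------
    validation_cohort = None
    if config.synthetic:
        spec = default_cohort_spec(seed=config.seed, n_samples=config.n_samples)
        cohort = generate_cohort(spec)
        layers = list(cohort.layers.values())
        expression = cohort.expression
        survival_table = cohort.survival
        # an independent validation cohort for the survival stage
        vspec = default_cohort_spec(
            seed=config.seed + 10_019, n_samples=config.n_samples
        )
        validation_cohort = generate_cohort(vspec)
        wide = pd.DataFrame({l.name: l.labels for l in layers})
        emit("layers.tsv", lambda p: wide.to_csv(p, sep="\t", na_rep=cio.NA_TOKEN))
        summary["latent_available"] = True
    else:
        layers = cio.read_layers(config.layers_path)
        expression = {
            name: cio.read_matrix(p) for name, p in config.expression_paths.items()
        }
        survival_table = (
            cio.read_survival(config.survival_path) if config.survival_path else None
        )
        summary["latent_available"] = False

    # ---- stage: membership + consensus ---------------------------------
    m = build_membership(layers, min_layers=config.min_layers)
    summary["n_samples_retained"] = int(len(m.samples))
    summary["n_samples_dropped"] = int(len(m.dropped))
    if m.dropped:
        emit(
            "dropped_samples.tsv",
            lambda p: pd.Series(m.dropped, name="sample").to_csv(p, sep="\t", index=False),
        )

    res = consensus_cluster(
        m,
        k_range=range(config.k_min, config.k_max + 1),
        reps=config.reps,
        subsample_frac=config.subsample_frac,
        seed=config.seed,
        select_by=config.select_by,
    )
    summary["chosen_k"] = int(res.chosen_k)
    summary["silhouette_by_k"] = {int(k): res.silhouette[k] for k in res.k_range}
    summary["silhouette_consensus_by_k"] = {
        int(k): res.silhouette_consensus[k] for k in res.k_range
    }
    summary["cdf_area_by_k"] = {int(k): res.cdf_area[k] for k in res.k_range}
    emit("coca_labels.tsv", lambda p: cio.write_labels(res.chosen_labels, p))
    emit(
        f"consensus_k{res.chosen_k}.tsv",
        lambda p: res.consensus[res.chosen_k].to_csv(p, sep="\t"),
    )
    profile = pd.DataFrame(
        {
            "k": res.k_range,
            "silhouette": [res.silhouette[k] for k in res.k_range],
            "silhouette_consensus": [res.silhouette_consensus[k] for k in res.k_range],
            "cdf_area": [res.cdf_area[k] for k in res.k_range],
            "delta_area": [res.delta_area[k] for k in res.k_range],
        }
    )
    emit("model_selection.tsv", lambda p: profile.to_csv(p, sep="\t", index=False))

    if config.synthetic:
        from sklearn.metrics import adjusted_rand_score

        latent = cohort.latent.loc[res.chosen_labels.index]
        summary["ari_vs_latent"] = float(
            adjusted_rand_score(latent, res.chosen_labels)
        )

    # ---- stage: association --------------------------------------------
    assoc = membership_phi(res.chosen_labels, layers, na_policy=config.na_policy)
    emit("association.tsv", lambda p: assoc.to_csv(p, sep="\t", index=False))
    top = assoc[assoc["rank"] == 1][["cluster", "layer", "level", "r"]]
    summary["top_association_per_cluster"] = [
        {k: (float(v) if k == "r" else str(v)) for k, v in row.items()}
        for row in top.to_dict("records")
    ]

    # ---- stage: signature ----------------------------------------------
    signature_features: list[str] = []
    if config.run_signature:
        subtype_labels = next(
            (l.labels for l in layers if l.name == config.subtype_layer), None
        )
        expr = expression.get(config.signature_expr)
        if subtype_labels is None or expr is None:
            raise ConfigError(
                f"signature stage needs layer {config.subtype_layer!r} and "
                f"expression matrix {config.signature_expr!r}"
            )
        pair = _modal_split_pair(res.chosen_labels, subtype_labels)
        if pair is None:
            logger.info("signature stage: no split pair of clusters found; skipped")
            summary["split_pair"] = None
        else:
            ca, cb, shared = pair
            summary["split_pair"] = {
                "cluster_a": str(ca), "cluster_b": str(cb), "shared_subtype": str(shared)
            }
            in_a = res.chosen_labels.index[
                (res.chosen_labels == ca)
                & (subtype_labels.reindex(res.chosen_labels.index) == shared)
            ]
            in_b = res.chosen_labels.index[
                (res.chosen_labels == cb)
                & (subtype_labels.reindex(res.chosen_labels.index) == shared)
            ]
            in_a = pd.Index(in_a).intersection(expr.columns)
            in_b = pd.Index(in_b).intersection(expr.columns)
            de = diffexp_two_group(
                expr, in_a, in_b,
                test=config.test, p_thresh=config.p_thresh, fc_thresh=config.fc_thresh,
            )
            signature_features = list(de.passing)
            summary["n_signature_features"] = len(signature_features)
            summary["split_group_sizes"] = [int(len(in_a)), int(len(in_b))]
            emit("signature_diffexp.tsv", lambda p: de.table.to_csv(p, sep="\t"))
            emit(
                "signature_features.tsv",
                lambda p: pd.Series(signature_features, name="feature").to_csv(
                    p, sep="\t", index=False
                ),
            )

    # ---- stage: survival validation ------------------------------------
    if config.run_survival and signature_features:
        if config.synthetic:
            vlayers = validation_cohort.layers
            vsubtype = vlayers[config.subtype_layer].labels
            modal = summary["split_pair"]["shared_subtype"]
            lumA_like = vsubtype.index[vsubtype == modal]
            vexpr = validation_cohort.expression[config.signature_expr]
            vexpr = vexpr[pd.Index(lumA_like).intersection(vexpr.columns)]
            vsurv = validation_cohort.survival
        else:
            vexpr = expression[config.signature_expr]
            vsurv = survival_table
        if vsurv is None:
            logger.info("survival stage: no survival table available; skipped")
        else:
            groups, missing = split_by_signature(vexpr, signature_features, k=2)
            surv = vsurv.loc[vsurv.index.intersection(groups.index)].copy()
            surv["group"] = groups.reindex(surv.index)
            stat, df_, p = logrank_test(surv, group_col="group")
            summary["logrank"] = {"statistic": float(stat), "df": int(df_), "p": float(p)}
            summary["signature_features_missing_in_validation"] = len(missing)
            try:
                hr = cox_hr(surv, group_col="group")
                term = hr.index[0]
                summary["cox"] = {
                    "hr": float(hr.loc[term, "hr"]),
                    "ci_lower": float(hr.loc[term, "ci_lower"]),
                    "ci_upper": float(hr.loc[term, "ci_upper"]),
                    "p": float(hr.loc[term, "p"]),
                }
            except (RuntimeError, ValueError) as exc:
                summary["cox"] = {"error": str(exc)}
            km = km_estimate(surv, group_col="group")
            for g, tab in km.items():
                emit(f"km_group{g}.tsv", lambda p, t=tab: t.to_csv(p, sep="\t"))
            emit("validation_groups.tsv", lambda p: cio.write_labels(groups, p))

    # ---- snapshot + manifest -------------------------------------------
    emit("config.yaml", lambda p: cio.write_config(asdict(config), p))
    manifest = {"config_hash": cfg_hash, "files": sorted(files)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
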