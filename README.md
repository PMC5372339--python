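# cocapipe

Multi-level **cluster-of-clusters (COCA)** integration of breast-tumor
classifications: from per-layer subtyping through consensus integration,
cluster–level association ranking, discriminating-signature derivation and
survival validation.

## The problem

Breast tumors are classified independently at several molecular levels —
mRNA expression subtypes, protein (RPPA) subtypes, miRNA expression
clusters, copy-number complexity groups, metabolic clusters, and
integrative (expression + copy-number) cluster schemes. Each level tells a
partial story, and the levels disagree in informative ways: a "higher-order"
grouping that integrates all of them can reveal splits inside established
subtypes — most notably inside luminal A, the largest and most heterogeneous
subtype. `cocapipe` is for computational biologists who have per-sample
categorical classification tables from two or more such levels (plus,
optionally, expression matrices and follow-up data) and want a tested,
reproducible integration pipeline.

## The method

Each of L layers assigns every sample a categorical label (with
missingness). Labels are one-hot encoded into a binary membership matrix,
and samples are compared with a missingness-normalized Manhattan distance

```
d(i, j) = (1/|O_ij|) Σ_{l ∈ O_ij} Σ_c |x_ilc − x_jlc|
        = 2 × (fraction of shared layers where i and j disagree),
```

where `O_ij` is the set of layers observed in both samples. Consensus
clustering (Ward linkage over repeated 80% subsamples) turns this into a
co-clustering frequency matrix per candidate K; the final grouping per K is
Ward on `1 − consensus`, and K is selected by the maximal average
silhouette width `s(i) = (b(i) − a(i)) / max(a(i), b(i))` on the
normalized Manhattan distance, with consensus-CDF curves as a supporting
criterion.

Downstream, every (layer, cluster) level is ranked against every integrated
cluster by the phi coefficient (Pearson correlation of 0/1 membership
vectors); the pair of integrated clusters sharing a modal subtype defines a
split, whose discriminating features are derived by Wilcoxon rank-sum tests
with Benjamini–Hochberg control (`adj p < 0.01`, `|log2FC| > 1`); and the
signature is validated by clustering an independent cohort's samples on
those features (Pearson distance, complete linkage, k = 2) and comparing the
groups with Kaplan–Meier curves, log-rank tests (optionally stratified) and
a covariate-adjusted Cox proportional-hazards fit.

The package also implements the single-layer classifiers feeding the
integration: correlation-based centroid subtyping with ER-weighted cohort
re-centering, nearest-shrunken-centroid assignment to fixed centroids,
copy-number complexity grouping (arms with score ≥ 0.5), recursive
gap-statistic partitioning (PART) of expression profiles, and metabolic
spectrum preprocessing with hierarchical clustering. A bundled synthetic
cohort generator produces six-group cohorts (five subtype-like groups plus
a planted miRNA-driven split of the largest one, with a 71-feature
signature and group-dependent survival) so the whole pipeline is testable
without any downloads. See `docs/methods.md` for details.

## Worked example

```bash
cocapipe run-all --seed 1 --outdir runs/demo
```

runs the full analysis on the default synthetic cohort and prints

```
{"chosen_k": 6, "n_samples_retained": 419}
```

419 of 420 samples had at least two observed layers and were integrated;
the average silhouette selected six consensus clusters. The run directory
contains `coca_labels.tsv` (integrated cluster per sample),
`model_selection.tsv` (silhouette and consensus-CDF profiles over K),
`association.tsv` (every level ranked per cluster by phi),
`signature_diffexp.tsv` / `signature_features.tsv` (the derived split
signature; 71 features at `adj p < 0.01`, `|log2FC| > 1`),
Kaplan–Meier step tables for the validation split, and `summary.json`:

```json
"split_pair": {"cluster_a": "2", "cluster_b": "3", "shared_subtype": "LumA"},
"n_signature_features": 71,
"logrank": {"statistic": 15.94, "df": 1, "p": 6.53e-05},
"cox": {"hr": 0.418, "ci_lower": 0.269, "ci_upper": 0.649}
```

Two integrated clusters share the luminal-A-like modal subtype — the
planted split. The 71 derived features separate an independent validation
cohort's luminal-A-like samples into groups with clearly different outcomes
(log-rank p ≈ 7 × 10⁻⁵; hazard ratio ≈ 2.4 between the groups — the
reported `hr` is for group 1 vs group 2, labeled by size, so values below 1
mean the larger group fares better).

The same stages are available piecewise (`cocapipe simulate`, `classify
caai|part|metabolic`, `coca`, `associate`, `signature`, `survival`) on
TSV inputs, and as library functions under `cocapipe.*`.

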