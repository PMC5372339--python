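# Methods

`cocapipe` implements a multi-level "cluster-of-clusters" (COCA) integration
of categorical tumor classifications, together with the single-layer
classifiers that produce those classifications, the association and
signature-derivation analyses that interpret the integrated clusters, and a
survival validation of the derived signature. This note describes the models
and procedures, the parameters that matter, the synthetic cohort the package
is tested on, and the numerical and design choices that were genuinely open.

## Single-layer classifiers

**Correlation-based centroid subtyping (mRNA).** A new cohort is aligned to
a training reference before centroid assignment: the cohort's *combined
centroid* is the ER-proportion-weighted average `c·mean(ER−) + (1−c)·mean(ER+)`
of its ER-negative and ER-positive mean expression vectors, where `c` is the
ER-negative proportion of the original training cohort. Each sample is
centered as `x − combined + training_centroid` and assigned to the reference
centroid with the largest Spearman correlation over shared genes (average
ranks for ties; a constant centered vector yields `unassigned`). Assignment
requires coverage of at least 90% of the model's genes by default. Because
Spearman correlation is rank-based, the assignment is invariant to adding a
constant to all genes of a sample.

**Nearest shrunken centroids (integrative clusters).** Class centroids
`x̄_k` are soft-thresholded toward the overall centroid:
`d_kj = (x̄_kj − x̄_j) / (m_k (s_j + s0))`, `d'_kj = sign(d_kj)·max(|d_kj| − Δ, 0)`,
`x̄'_kj = x̄_j + m_k (s_j + s0) d'_kj`, and samples are assigned by the
discriminant `δ_k(x) = Σ_j (x_j − x̄'_kj)² / (s_j + s0)² − 2 log π_k`
(argmin; ties break to the lowest class index and are flagged). `Δ` defaults
to 0 — pure nearest-centroid on the given centroids in `(s+s0)`-standardized
space — because published centroid sets rarely state the shrinkage used;
both `Δ` and the priors `π_k` are configurable (uniform priors by default).
A companion `normalize_to_reference` rescales each feature of a new cohort
to a reference mean and standard deviation before assignment.

**Copy-number complexity grouping.** Per-chromosome-arm complexity scores
are reduced to the number of arms with a score at or above the threshold
τ = 0.5, capped into the labels "0", "1", "2"(+). The boundary convention is
`score ≥ τ` counts as an event, making the label monotone in every score.

**Recursive partitioning (miRNA).** `part_cluster` recursively splits a
hierarchical dendrogram: at each node a flat cut at `k ∈ 1..Kmax` is scored
by the gap statistic — `gap(k) = mean_b log W_k(ref_b) − log W_k(data)` with
`W_k` the within-cluster dispersion `Σ_r D_r / (2 n_r)` under the configured
distance, reference datasets drawn uniformly per feature over observed
ranges, and `se(k) = sd_b · sqrt(1 + 1/B)`. The selected k is the first with
`gap(k) ≥ gap(k+1) − se(k+1)`. A node becomes a leaf when k = 1 or a child
would fall below `minSize`; leaves are numbered in depth-first discovery
order, so clusters can originate at different dendrogram heights. Defaults
(`Kmax=4, minSize=41, B=1000`, Pearson distance, complete linkage) match the
published miRNA analysis; tests use smaller `minSize`/`B` for speed. The gap
criterion itself is a documented package choice: the original analysis names
only the software it used, not the internal split score.

**Metabolic spectra.** Spectra are restricted to 1.40–4.70 ppm, five
lipid-dominated windows (4.27–4.36, 2.70–2.88, 2.20–2.30, 1.93–2.09,
1.50–1.67 ppm) are excluded, and each sample's retained vector is divided by
its own mean (row means equal 1 to machine precision). Clustering uses
Euclidean distance with Ward linkage, cut at k = 3 by default.

## Integration

Per-layer labels are one-hot encoded into a samples × (layer, cluster)
binary membership matrix with a per-(sample, layer) observed mask. Samples
observed in fewer than `min_layers = 2` layers are dropped and reported.

The **missingness-normalized Manhattan distance** between samples i and j
averages the Manhattan distance of the one-hot blocks over the layers
observed in *both* samples:
`d(i,j) = (1/|O_ij|) Σ_{l∈O_ij} Σ_c |x_ilc − x_jlc| = 2 × (fraction of
shared layers with disagreeing labels)`, hence `d ∈ [0, 2]`. Dividing by the
number of shared observed layers keeps layers with many missing values
comparable to complete ones — the stated goal of the original normalization,
whose exact formula is not published. Pairs sharing no layer get distance 2
with a warning.

**Consensus clustering** draws `reps` subsamples of `⌈frac·n⌉` samples
without replacement (defaults 1000 × 0.8), Ward-clusters each on the
normalized Manhattan distance at every K in 2..10, and sets
`consensus(i,j)` = co-clustering count / co-sampling count (never co-sampled
pairs → 0 with a warning; vanishingly rare at the defaults). Final labels
per K come from Ward clustering of `1 − consensus`. Ward on these
non-Euclidean distances uses the standard Lance–Williams update.

**Choice of K.** The average silhouette width of the final grouping is
computed on the normalized Manhattan distance, and K is its argmax
(`select_by="distance"`, the default). A silhouette on `1 − consensus` and
the consensus-CDF area / delta-area curves are also reported as supporting
criteria. The distance-based silhouette is the primary criterion because it
scores the grouping against the data rather than against the resampling's
own stability; the stability silhouette saturates near 1 for any K whose
cut is stable and is therefore reported but not used for selection.

Per-sample silhouettes use `s(i) = (b(i) − a(i)) / max(a(i), b(i))` with
singletons set to 0.

## Association and signature derivation

Cluster–level association uses the **phi coefficient** — the Pearson
correlation of two 0/1 membership vectors, equal to the standardized 2×2
contingency association. Under the default `na_policy="zero"` a sample
missing a layer is coded 0 for all of that layer's levels (it belongs to
none of them); `"complete"` drops such samples per layer. Both are exposed
because published correlations of this kind rarely state the convention.
Every supplied level is ranked per cluster, descending in r. Clinical
associations use chi-squared tests on cluster-membership × category tables
without continuity correction, Bonferroni-adjusted over the family of tests
actually performed, with expected-count warnings below 5.

Signature derivation between two clusters applies a two-sided Wilcoxon
rank-sum test per feature (exact for small groups without ties, via SciPy;
Welch t selectable), Benjamini–Hochberg adjustment across features, and
`log2FC` as the difference of group means of log2 values. A feature passes
at `adjusted p < 0.01` and `|log2FC| > 1` by default. One-vs-rest
comparisons apply the same test per cluster with BH within each comparison.
`spearman_filter` retains genes whose best |Spearman rho| against any
signature feature exceeds 0.4; `geneset_enrichment` performs one-sided
Fisher exact tests over user-supplied gene sets (GMT) with BH across sets —
a generic replacement for proprietary pathway databases.

In the orchestrated run, the split pair is found automatically as the two
integrated clusters sharing the same modal subtype label in a designated
layer (default `pam50`); the comparison is restricted to each cluster's
samples of that shared subtype, mirroring how a luminal-A split would be
analysed.

## Survival validation

Samples are clustered on the signature features with Pearson distance and
complete linkage, cut at k = 2, and the groups are labeled by size — never
reoriented by outcome before testing. Missing signature features are
reported. The Kaplan–Meier product-limit estimator is computed in-package
with confidence bands from the Greenwood variance on the log-survival
scale. The multi-group log-rank test accumulates observed-minus-expected
event counts and their covariance over the pooled risk set, per stratum
when stratified, summing across strata before forming the chi-squared
statistic on G−1 groups (for two groups without ties this reduces to the
squared standardized O−E statistic). Proportional-hazards fits are
delegated to lifelines' `CoxPHFitter` (Efron handling of ties, Wald CIs);
the hazard ratio is `exp(coef)` for the group indicator. Tied-time handling
by Efron's approximation is a package choice; the endpoint is treated as
standard right-censored time-to-event throughout.

## Synthetic cohort

The generator produces cohorts with the statistical structure the analysis
assumes, so every stage is testable without downloads.

* **Latent structure.** n = 420 samples in six groups: two luminal-A-like
  halves of 75 and 82 samples (proportions follow the real split cluster
  sizes), and luminal-B-like (106), basal-like (54), HER2-like (50) and
  normal-like (53) groups, allocated by largest-remainder rounding and
  shuffled by seed.
* **Layers.** Seven classification layers are drawn from per-group
  confusion rows and masked missing independently per (sample, layer). The
  mRNA-subtype layer (3% noise, 4% missing) and miRNA layer (1.5–5% noise,
  0.5% missing) are confidently informative for every group; the protein,
  integrative-cluster and pathway layers are confident for some groups and
  diffuse for the rest; the copy-number-complexity and metabolic layers are
  weakly informative throughout; the five non-driving supporting layers
  carry 20% missingness, mirroring the real pattern in which only the miRNA
  level is near-complete. This partial-informativeness design places the
  six groups at comparable pairwise separations in the normalized Manhattan
  metric rather than in a nested hierarchy — the regime in which an average
  silhouette can resolve a split carried by a single layer, and the regime
  the real integrated tables exhibit (heavily overlapping classifications).
  The parameters were fixed by this design analysis and then frozen.
* **The split.** The two halves differ *only* in (i) the driving miRNA
  layer's labels, (ii) a 1.5 log2-unit mean difference on 71 signature
  features, and (iii) survival hazard. This contract is enforced by spec
  validation (non-driving confusion rows must be identical between halves)
  and by construction of the expression matrices (the halves share one
  marker block). Signature effects are symmetric (±effect/2 per half) with
  ~80% of features up in the first half: real split signatures contain both
  directions, and a direction-free uniform shift would be invisible to the
  correlation-based validation clustering.
* **Expression.** Each matrix is marker-block structured (per latent group,
  halves merged) plus i.i.d. Gaussian noise of sd 0.5 on log2 scale — the
  simplest model consistent with log2-transformed, normalized array data.
  The mRNA matrix adds 40 genes linearly coupled to signature features for
  correlation-filter testing. Realistic array noise (probe effects,
  batch structure, heteroskedasticity) is deliberately not modeled, so
  passing tests demonstrate correctness of the procedures under their
  assumptions, not robustness to real-array artefacts.
* **Copy-number scores.** Per-arm scores are drawn consistently with the
  drawn complexity label (0, 1, or 2–4 arms above threshold), so the
  grouping operation recovers the label exactly.
* **Survival.** Event times are exponential with per-group hazards (the
  halves at 0.04 vs 0.10 per time unit, hazard ratio 2.5, matching the
  scale of the reported adjusted hazard ratio); censoring is independent
  exponential with hazard `h_g · r/(1−r)`, which makes the expected
  censored fraction exactly the configured rate `r` (default 0.3) and
  reduces to no censoring at r = 0. A two-level hospital stratum and a
  binary treatment covariate are attached, independent of outcome, for
  adjustment exercises.
* **Reproducibility.** One integer seed fans out to fixed-offset child
  streams (latent order, each layer, each matrix, scores, survival), so the
  same spec and seed yield byte-identical cohorts, and components can be
  regenerated independently.

## Problem sizes and numerical choices

The bundled tests and the acceptance script run the full analysis at the
default cohort size (n = 420) with 200 consensus repetitions, recursive
partitioning with `B = 50` references, 500-replicate null calibrations for
the log-rank and chi-squared tests, and a 20-seed power analysis for the
signature thresholds; these sizes were chosen so the complete suite
executes in a few minutes on a single core while keeping every estimate's
Monte-Carlo error well inside the asserted tolerances. Degenerate inputs
are handled explicitly: constant features get p = 1 in differential
expression and are set to the reference mean in normalization; constant
centered vectors are `unassigned`; zero within-cluster dispersion makes the
gap statistic recommend k = 1; sample pairs sharing no layer get the
maximal distance with a warning. Oracle-equivalence tests require exact
agreement (within 1e−10) with brute-force reimplementations of the
normalized Manhattan distance, phi, NSC shrinkage/discriminants,
silhouette, the exact Wilcoxon tail, the Fisher/hypergeometric tail and BH.

## Known limitations

* The consensus resampling scheme (item resampling, 80% fraction) and the
  K-selection silhouette are documented package choices; published COCA
  analyses name their software but not these settings, so exact numerical
  reproduction of a given cohort's consensus result may require matching
  those settings.
* Real multi-level data carry correlated missingness (platform
  availability is driven by material, not coin flips) and correlated label
  noise across layers; the generator's independence assumptions are
  simplifications.
* Complexity-score computation from segmented copy-number profiles, array
  preprocessing, probe-to-gene collapsing and pathway-database content are
  out of scope; the package consumes their outputs.
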