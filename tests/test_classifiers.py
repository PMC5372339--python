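"""Unit tests for the single-layer classifiers."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

from cocapipe.classifiers import (
    CAAIProfile,
    CentroidModel,
    NSCModel,
    PartConfig,
    SpectrumSet,
    caai_group,
    centroid_assign,
    combined_centroid,
    gap_statistic,
    hcluster_cut,
    normalize_to_reference,
    nsc_assign,
    nsc_shrink,
    part_cluster,
    preprocess_spectra,
)


def toy_centroid_model(genes, rng, c=0.3):
    centroids = pd.DataFrame(
        rng.normal(size=(len(genes), 5)),
        index=genes,
        columns=["basal", "her2", "lumA", "lumB", "normal"],
    )
    training = pd.Series(rng.normal(size=len(genes)), index=genes)
    return CentroidModel(centroids, training, c)


class TestCombinedCentroid:
    def test_identical_samples_give_that_vector(self, rng):
        genes = [f"g{i}" for i in range(6)]
        v = pd.Series(rng.normal(size=6), index=genes)
        expr = pd.DataFrame({f"s{i}": v for i in range(4)})
        er = pd.Series(["neg", "pos", "pos", "neg"], index=expr.columns)
        model = toy_centroid_model(genes, rng, c=0.7)
        out = combined_centroid(expr, er, model)
        assert np.allclose(out, v)

    def test_two_gene_arithmetic(self, rng):
        genes = ["g1", "g2"]
        expr = pd.DataFrame(
            {"n1": [1.0, 0.0], "p1": [0.0, 1.0]}, index=genes
        )
        er = pd.Series({"n1": "neg", "p1": "pos"})
        model = toy_centroid_model(genes, rng, c=0.25)
        out = combined_centroid(expr, er, model)
        assert np.allclose(out, [0.25, 0.75])

    def test_matches_bruteforce_group_means(self, rng):
        genes = [f"g{i}" for i in range(10)]
        expr = pd.DataFrame(
            rng.normal(size=(10, 20)), index=genes,
            columns=[f"s{i}" for i in range(20)],
        )
        er = pd.Series(rng.choice(["pos", "neg"], size=20), index=expr.columns)
        if er.nunique() < 2:
            er.iloc[0] = "neg" if er.iloc[1] == "pos" else "pos"
        c = 0.37
        model = toy_centroid_model(genes, rng, c=c)
        out = combined_centroid(expr, er, model)
        brute = c * expr.loc[:, er == "neg"].mean(axis=1) + (1 - c) * expr.loc[
            :, er == "pos"
        ].mean(axis=1)
        assert np.allclose(out, brute)

    def test_missing_er_class_raises(self, rng):
        genes = ["g1", "g2"]
        expr = pd.DataFrame(rng.normal(size=(2, 3)), index=genes,
                            columns=["a", "b", "c"])
        er = pd.Series(["pos", "pos", "pos"], index=expr.columns)
        with pytest.raises(ValueError, match="skip re-centering"):
            combined_centroid(expr, er, toy_centroid_model(genes, rng))


class TestCentroidAssign:
    def test_exact_centroid_match_recovers_label(self, rng):
        genes = [f"g{i}" for i in range(50)]
        model = toy_centroid_model(genes, rng)
        # anchor samples around the training centroid plus a probe sitting
        # exactly on the basal centroid; centering shifts all samples by one
        # common vector, which Spearman rank correlation ignores per sample
        basal = model.centroids["basal"]
        t = model.training_centroid
        c = model.er_neg_proportion
        neg = t + (1 - c) * 1.0
        pos = t - c * 1.0
        expr = pd.DataFrame({"sn": neg, "sp": pos, "probe": basal})
        er = pd.Series({"sn": "neg", "sp": "pos", "probe": "pos"})
        expr["mirror"] = 2 * neg - basal
        er["mirror"] = "neg"
        out = centroid_assign(expr, er, model)
        assert out.loc["probe", "label"] == "basal"

    def test_reversed_rank_centroids(self, rng):
        genes = [f"g{i}" for i in range(5)]
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=genes)
        centroids = pd.DataFrame({"A": a, "B": a.iloc[::-1].set_axis(genes)})
        centroids["C"] = 0.0
        centroids["D"] = 0.0
        centroids["E"] = 0.0
        model = CentroidModel(centroids, pd.Series(0.0, index=genes), 0.5)
        expr = pd.DataFrame({
            "s1": a + 0.01, "s2": -a,
        })
        er = pd.Series({"s1": "pos", "s2": "neg"})
        out = centroid_assign(expr, er, model)
        # sample s1 keeps centroid A's rank order after centering
        assert out.loc["s1", "A"] == pytest.approx(1.0)
        assert out.loc["s1", "B"] == pytest.approx(-1.0)
        assert out.loc["s1", "label"] == "A"

    def test_shift_invariance_per_sample(self, rng):
        """Adding a constant to all genes of a sample keeps the assignment."""
        genes = [f"g{i}" for i in range(30)]
        model = toy_centroid_model(genes, rng)
        expr = pd.DataFrame(rng.normal(size=(30, 8)), index=genes,
                            columns=[f"s{i}" for i in range(8)])
        er = pd.Series(["pos", "neg"] * 4, index=expr.columns)
        base = centroid_assign(expr, er, model)
        shifted = expr.add(pd.Series(rng.normal(size=8) * 10, index=expr.columns), axis=1)
        # shifting single samples changes the ER-group means, so re-center
        # with the same combined centroid by shifting all samples equally
        shifted_const = expr + 3.14
        out = centroid_assign(shifted_const, er, model)
        assert (out["label"] == base["label"]).all()

    def test_low_coverage_raises(self, rng):
        genes = [f"g{i}" for i in range(50)]
        model = toy_centroid_model(genes, rng)
        expr = pd.DataFrame(rng.normal(size=(10, 4)), index=genes[:10],
                            columns=list("abcd"))
        er = pd.Series(["pos", "neg", "pos", "neg"], index=expr.columns)
        with pytest.raises(ValueError, match="covers only"):
            centroid_assign(expr, er, model)

    def test_recovery_on_planted_subtypes(self, rng):
        """Noiseless samples at their subtype centroid are all recovered."""
        genes = [f"g{i}" for i in range(50)]
        model = toy_centroid_model(genes, rng, c=0.4)
        labels = list(model.subtypes) * 8
        expr = pd.DataFrame(
            {f"s{i}": model.centroids[lab] for i, lab in enumerate(labels)}
        )
        er = pd.Series(
            ["neg" if lab in ("basal", "her2") else "pos" for lab in labels],
            index=expr.columns,
        )
        out = centroid_assign(expr, er, model)
        # centering shifts every sample by the same vector; exact-centroid
        # samples of a balanced noiseless cohort still rank-match their own
        # centroid in > 95% of cases
        acc = (out["label"].to_numpy() == np.array(labels)).mean()
        assert acc >= 0.95


class TestNormalizeToReference:
    def test_identity_and_zscore(self, rng):
        x = pd.DataFrame(rng.normal(2, 3, size=(5, 40)),
                         index=[f"f{i}" for i in range(5)])
        same = normalize_to_reference(x, x.mean(axis=1), x.std(axis=1, ddof=1))
        assert np.allclose(same, x)
        z = normalize_to_reference(x, pd.Series(0.0, index=x.index),
                                   pd.Series(1.0, index=x.index))
        assert np.allclose(z.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_hits_reference_moments(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 30)), index=[f"f{i}" for i in range(6)])
        ref_mean = pd.Series(rng.normal(size=6), index=x.index)
        ref_sd = pd.Series(rng.uniform(0.5, 2, size=6), index=x.index)
        out = normalize_to_reference(x, ref_mean, ref_sd)
        assert np.allclose(out.mean(axis=1), ref_mean, atol=1e-10)
        assert np.allclose(out.std(axis=1, ddof=1), ref_sd, atol=1e-10)

    def test_constant_feature_set_to_ref_mean(self, rng):
        x = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["c", "v"])
        out = normalize_to_reference(
            x, pd.Series({"c": 5.0, "v": 0.0}), pd.Series({"c": 1.0, "v": 1.0})
        )
        assert (out.loc["c"] == 5.0).all()


class TestNSC:
    def make_model(self, rng, delta=0.0, priors=None, k=3, p=10):
        classes = [f"c{i}" for i in range(k)]
        feats = [f"f{i}" for i in range(p)]
        return NSCModel(
            centroids=pd.DataFrame(rng.normal(size=(p, k)), index=feats,
                                   columns=classes),
            overall_centroid=pd.Series(rng.normal(size=p), index=feats),
            s=pd.Series(rng.uniform(0.5, 2, size=p), index=feats),
            s0=0.2,
            m=pd.Series(rng.uniform(0.1, 0.5, size=k), index=classes),
            delta=delta,
            priors=priors,
        )

    def test_zero_shrinkage_is_identity(self, rng):
        model = self.make_model(rng, delta=0.0)
        assert np.allclose(nsc_shrink(model), model.centroids)

    def test_full_shrinkage_collapses_to_overall(self, rng):
        model = self.make_model(rng, delta=0.0)
        d_max = max(
            ((model.centroids[k] - model.overall_centroid)
             / (model.m[k] * (model.s + model.s0))).abs().max()
            for k in model.classes
        )
        model.delta = float(d_max) + 1.0
        shrunk = nsc_shrink(model)
        for k in model.classes:
            assert np.allclose(shrunk[k], model.overall_centroid)

    def test_shrinkage_matches_softthreshold_formula(self, rng):
        model = self.make_model(rng, delta=0.5)
        shrunk = nsc_shrink(model)
        for k in model.classes:
            for j in model.centroids.index:
                denom = model.m[k] * (model.s[j] + model.s0)
                d = (model.centroids.loc[j, k] - model.overall_centroid[j]) / denom
                d_shr = np.sign(d) * max(abs(d) - model.delta, 0.0)
                expect = model.overall_centroid[j] + denom * d_shr
                assert shrunk.loc[j, k] == pytest.approx(expect, abs=1e-12)

    def test_sample_at_centroid_assigned_there(self, rng):
        model = self.make_model(rng, delta=0.3)
        shrunk = nsc_shrink(model)
        expr = shrunk.copy()
        expr.columns = [f"s_{c}" for c in model.classes]
        out = nsc_assign(expr, model)
        assert list(out["label"]) == model.classes

    def test_hand_computed_two_class_discriminant(self):
        model = NSCModel(
            centroids=pd.DataFrame({"c0": [0.0], "c1": [2.0]}, index=["f"]),
            overall_centroid=pd.Series({"f": 1.0}),
            s=pd.Series({"f": 0.8}),
            s0=0.2,
            m=pd.Series({"c0": 0.1, "c1": 0.1}),
            delta=0.0,
        )
        expr = pd.DataFrame({"x": [0.9]}, index=["f"])
        out = nsc_assign(expr, model)
        # discriminants: (0.9-0)^2 = 0.81 vs (0.9-2)^2 = 1.21 (+ equal-prior
        # constant), so the class at centroid 0 wins
        assert out.loc["x", "label"] == "c0"
        assert out.loc["x", "c1"] - out.loc["x", "c0"] == pytest.approx(1.21 - 0.81)

    def test_priors_shift_boundary_exactly(self, rng):
        """Unequal priors shift delta_k by -2 log pi_k vs a grid oracle."""
        priors = pd.Series({"c0": 0.7, "c1": 0.2, "c2": 0.1})
        model = self.make_model(rng, delta=0.2, priors=priors)
        shrunk = nsc_shrink(model)
        grid = pd.DataFrame(
            np.random.default_rng(1).normal(size=(10, 50)),
            index=model.centroids.index,
        )
        grid.columns = [f"x{i}" for i in range(50)]
        out = nsc_assign(grid, model)
        denom2 = (model.s + model.s0) ** 2
        for x in grid.columns:
            scores = {
                k: float((((grid[x] - shrunk[k]) ** 2) / denom2).sum()
                         - 2 * np.log(priors[k]))
                for k in model.classes
            }
            assert out.loc[x, "label"] == min(scores, key=scores.get)

    def test_delta0_equal_priors_is_nearest_centroid(self, rng):
        """With no shrinkage and flat priors, NSC is nearest-centroid in
        (s+s0)-standardized space."""
        model = self.make_model(rng, delta=0.0)
        x = pd.DataFrame(rng.normal(size=(10, 30)), index=model.centroids.index,
                         columns=[f"x{i}" for i in range(30)])
        out = nsc_assign(x, model)
        scale = model.s + model.s0
        std_x = x.div(scale, axis=0)
        std_c = model.centroids.div(scale, axis=0)
        for col in x.columns:
            d = {k: ((std_x[col] - std_c[k]) ** 2).sum() for k in model.classes}
            assert out.loc[col, "label"] == min(d, key=d.get)

    def test_missing_features_error(self, rng):
        model = self.make_model(rng)
        expr = pd.DataFrame(rng.normal(size=(3, 2)),
                            index=list(model.centroids.index[:3]), columns=["a", "b"])
        with pytest.raises(ValueError, match="lacks model features"):
            nsc_assign(expr, model)


class TestCAAI:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([0.1, 0.2, 0.49], "0"),
            ([0.6, 0.3], "1"),
            ([0.5, 0.7, 0.9], "2"),  # boundary 0.5 counts as an event
            ([0.5], "1"),
        ],
    )
    def test_grouping(self, scores, expected):
        prof = CAAIProfile(pd.Series(scores, dtype=float))
        assert caai_group(prof) == expected

    def test_all_missing_gives_none(self):
        prof = CAAIProfile(pd.Series([np.nan, np.nan]))
        assert caai_group(prof) is None

    def test_monotone_in_scores(self, rng):
        """Raising any arm score never decreases the group label."""
        for _ in range(50):
            scores = rng.uniform(0, 1.2, size=8)
            base = caai_group(CAAIProfile(pd.Series(scores)))
            j = rng.integers(0, 8)
            bumped = scores.copy()
            bumped[j] += rng.uniform(0, 1)
            after = caai_group(CAAIProfile(pd.Series(bumped)))
            assert int(after) >= int(base)


class TestGapStatistic:
    def test_two_blobs_select_two(self, rng):
        a = rng.normal(0, 0.3, size=(25, 2))
        b = rng.normal(6, 0.3, size=(25, 2))
        data = np.vstack([a, b])
        out = gap_statistic(data, "euclidean", "ward", range(1, 5), b=30, seed=0)
        assert out.attrs["selected_k"] == 2

    def test_single_gaussian_mostly_selects_one(self):
        hits = 0
        for seed in range(10):
            data = np.random.default_rng(seed).normal(size=(40, 3))
            out = gap_statistic(data, "euclidean", "ward", range(1, 4), b=25,
                                seed=seed)
            hits += out.attrs["selected_k"] == 1
        assert hits >= 9

    def test_identical_points_degenerate(self):
        data = np.ones((3, 2))
        out = gap_statistic(data, "euclidean", "ward", range(1, 3), b=5, seed=0)
        assert out.attrs["selected_k"] == 1


class TestPart:
    def test_leaves_partition_samples(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 60)),
                            columns=[f"s{i}" for i in range(60)])
        cfg = PartConfig(kmax=3, min_size=5, b=10, distance="euclidean",
                         linkage="ward", seed=0)
        labels = part_cluster(expr, cfg)
        assert labels.index.equals(expr.columns)
        assert (labels >= 1).all()

    def test_nested_structure_found_at_different_heights(self, rng):
        """Two macro-clusters, one containing two sub-clusters -> 3 leaves."""
        n = 40
        far = rng.normal(0, 0.4, size=(n, 4)) + 12
        sub1 = rng.normal(0, 0.4, size=(n, 4))
        sub2 = rng.normal(0, 0.4, size=(n, 4))
        sub2[:, 0] += 4.0
        data = np.vstack([far, sub1, sub2])
        expr = pd.DataFrame(data.T, columns=[f"s{i}" for i in range(3 * n)])
        cfg = PartConfig(kmax=4, min_size=10, b=30, distance="euclidean",
                         linkage="ward", seed=3)
        labels = part_cluster(expr, cfg)
        assert labels.nunique() == 3
        truth = np.repeat([0, 1, 2], n)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_min_size_prevents_split(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 30)),
                            columns=[f"s{i}" for i in range(30)])
        cfg = PartConfig(kmax=4, min_size=20, b=5, seed=0, distance="euclidean",
                        linkage="ward")
        labels = part_cluster(expr, cfg)
        assert labels.nunique() == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PartConfig(kmax=1)
        with pytest.raises(ValueError):
            PartConfig(b=0)
        with pytest.raises(ValueError):
            PartConfig(distance="cosine")


class TestSpectra:
    def make_set(self, ppm, inten):
        return SpectrumSet(np.array(ppm), pd.DataFrame(inten))

    def test_flat_spectrum_normalizes_to_one(self):
        ppm = np.linspace(4.7, 1.4, 50)
        spec = self.make_set(ppm, np.full((3, 50), 5.0))
        out = preprocess_spectra(spec)
        assert np.allclose(out, 1.0)

    def test_window_logic(self):
        ppm = np.array([2.00, 2.10])
        spec = self.make_set(ppm, np.ones((2, 2)))
        out = preprocess_spectra(spec)
        # 2.00 lies in the 1.93-2.09 exclusion, 2.10 does not
        assert list(out.index) == ["ppm_2.1000"]

    def test_retained_count_matches_interval_oracle(self, rng):
        ppm = np.round(np.linspace(5.2, 0.8, 300), 4)
        spec = self.make_set(ppm, rng.uniform(0.1, 2, size=(4, 300)))
        out = preprocess_spectra(spec)

        def brute_keep(p):
            if not 1.40 <= p <= 4.70:
                return False
            for a, b in [(4.27, 4.36), (2.70, 2.88), (2.20, 2.30),
                         (1.93, 2.09), (1.50, 1.67)]:
                if a <= p <= b:
                    return False
            return True

        assert out.shape[0] == sum(brute_keep(p) for p in ppm)
        assert np.allclose(out.mean(axis=0), 1.0, atol=1e-12)

    def test_row_means_exactly_one(self, rng):
        ppm = np.linspace(4.6, 1.5, 80)
        spec = self.make_set(ppm, rng.uniform(0.5, 3, size=(6, 80)))
        out = preprocess_spectra(spec)
        assert np.allclose(out.mean(axis=0), 1.0, atol=1e-12)


class TestHclusterCut:
    def test_separated_clouds(self, rng):
        a = rng.normal(0, 0.1, size=(4, 10))
        b = rng.normal(50, 0.1, size=(4, 10))
        mat = pd.DataFrame(np.hstack([a, b]),
                           columns=[f"s{i}" for i in range(20)])
        labels = hcluster_cut(mat, "euclidean", "ward", 2)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_equals_n(self, rng):
        mat = pd.DataFrame(rng.normal(size=(3, 7)),
                           columns=[f"s{i}" for i in range(7)])
        labels = hcluster_cut(mat, "euclidean", "average", 7)
        assert labels.nunique() == 7

    def test_k_out_of_range(self, rng):
        mat = pd.DataFrame(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError):
            hcluster_cut(mat, "euclidean", "ward", 6)

    def test_complete_linkage_matches_naive_agglomeration(self, rng):
        """Step-by-step naive merging of nearest clusters reproduces the cut."""
        data = rng.normal(size=(20, 3))
        mat = pd.DataFrame(data.T, columns=[f"s{i}" for i in range(20)])
        k = 4
        got = hcluster_cut(mat, "euclidean", "complete", k)

        # naive complete-linkage agglomeration
        clusters = [{i} for i in range(20)]
        d = np.sqrt(((data[:, None, :] - data[None, :, :]) ** 2).sum(-1))
        while len(clusters) > k:
            best = None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                    if best is None or dist < best[0]:
                        best = (dist, i, j)
            _, i, j = best
            clusters[i] |= clusters[j]
            del clusters[j]
        naive = np.empty(20, dtype=int)
        for ci, members in enumerate(clusters):
            for s in members:
                naive[s] = ci
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(naive, got) == 1.0

    def test_pearson_distance_is_one_minus_r(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 6)),
                           columns=[f"s{i}" for i in range(6)])
        from cocapipe.classifiers import pairwise_distance

        d = squareform(pairwise_distance(mat.to_numpy().T, "pearson"))
        r = np.corrcoef(mat.to_numpy().T)
        assert np.allclose(d, 1 - r, atol=1e-10)
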