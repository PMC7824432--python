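"""Clustering, semantic labels, shares, isomap, and culture timelines."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from dic_cellscope.core import ParameterError
from dic_cellscope.morphometry import FEATURE_COLUMNS, build_feature_table
from dic_cellscope.population import (
    ClusterParams,
    ClusterResult,
    assign_semantics,
    cluster_shares,
    fit_kmeans,
    isomap_embed,
    timeline_summary,
)
from dic_cellscope.synthetic import make_scene, render_dic


def table_from(X, **extra):
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=list(FEATURE_COLUMNS))
    for k, v in extra.items():
        df[k] = v
    return df


def blobs(rng, centers, n_per, sigma=0.1):
    X = np.vstack([
        c + sigma * rng.standard_normal((n_per, len(c))) for c in centers
    ])
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y


class TestFitKmeans:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        centers = np.zeros((3, 6))
        centers[1, 0] = centers[2, 1] = 10.0
        X, y = blobs(rng, centers, 100)
        res = fit_kmeans(table_from(X), ClusterParams(standardize=False))
        assert res.k == 3
        # partition identical to blob identity up to relabeling
        mapping = {}
        for cid, truth in zip(res.assignment, y):
            mapping.setdefault(cid, truth)
            assert mapping[cid] == truth

    def test_deterministic_bit_exact(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 6))
        a = fit_kmeans(table_from(X), ClusterParams(rng_seed=5))
        b = fit_kmeans(table_from(X), ClusterParams(rng_seed=5))
        np.testing.assert_array_equal(a.assignment, b.assignment)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.inertia == b.inertia

    def test_too_few_distinct_rows(self):
        X = np.array([[0.0] * 6, [1.0] * 6] * 5)
        with pytest.raises(ParameterError):
            fit_kmeans(table_from(X), ClusterParams(k=3))

    def test_matches_exhaustive_partition_search(self):
        """On tiny instances the fitted inertia equals the global optimum
        found by enumerating every 2-partition."""
        rng = np.random.default_rng(7)
        for trial in range(5):
            X = rng.standard_normal((7, 2))
            res = fit_kmeans(X, ClusterParams(k=2, n_restarts=20, rng_seed=trial,
                                              standardize=False))
            best = np.inf
            for labels in itertools.product([0, 1], repeat=len(X)):
                labels = np.array(labels)
                if len(set(labels)) < 2:
                    continue
                cost = sum(
                    ((X[labels == c] - X[labels == c].mean(0)) ** 2).sum()
                    for c in (0, 1)
                )
                best = min(best, cost)
            assert res.inertia == pytest.approx(best, rel=1e-9)

    def test_agrees_with_sklearn(self):
        """Independent route: sklearn's k-means reaches the same inertia on
        well-separated data."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(3)
        centers = rng.uniform(-5, 5, size=(3, 6))
        X, _ = blobs(rng, centers, 50, sigma=0.3)
        ours = fit_kmeans(X, ClusterParams(standardize=False))
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.inertia == pytest.approx(sk.inertia_, rel=1e-6)


class TestAssignSemantics:
    @staticmethod
    def result_with_counts(counts, ecc_means, major_means=None):
        """Synthesize a ClusterResult + table with given cluster sizes."""
        k = len(counts)
        assignment = np.repeat(np.arange(k), counts)
        rng = np.random.default_rng(0)
        ecc = np.concatenate([
            np.full(c, e) for c, e in zip(counts, ecc_means)
        ]) + 1e-4 * rng.standard_normal(sum(counts))
        major = np.concatenate([
            np.full(c, m) for c, m in zip(counts, major_means or ecc_means)
        ])
        table = pd.DataFrame({
            "eccentricity": ecc, "major_axis": major,
        })
        res = ClusterResult(
            centroids=np.zeros((k, 6)), assignment=assignment, inertia=0.0
        )
        return res, table

    def test_reference_cluster_sizes(self):
        """With sizes 4641/1320/119 the 119-cluster is the conglomerate
        (green) group; high-eccentricity cluster is red."""
        res, table = self.result_with_counts(
            (4641, 1320, 119), ecc_means=(0.4, 0.95, 0.7)
        )
        out = assign_semantics(res, table)
        assert out.semantic == {0: "blue", 1: "red", 2: "green"}

    def test_invariant_to_cluster_relabeling(self):
        res, table = self.result_with_counts(
            (119, 4641, 1320), ecc_means=(0.7, 0.4, 0.95)
        )
        out = assign_semantics(res, table)
        assert out.semantic == {0: "green", 1: "blue", 2: "red"}

    def test_eccentricity_tie_breaks_on_major_axis(self):
        res, table = self.result_with_counts(
            (100, 100, 10), ecc_means=(0.5, 0.5, 0.5),
            major_means=(1.0, 2.0, 1.0),
        )
        table["eccentricity"] = 0.5  # exact tie
        out = assign_semantics(res, table)
        assert out.semantic[1] == "red"  # longer cells
        assert out.semantic[0] == "blue"
        assert out.semantic[2] == "green"

    def test_fiber_majority_cluster_is_red(self):
        """On generated mixed cultures the cluster dominated by fiber cells
        (by ground truth) receives the red label."""
        scenes = [make_scene(9, 3, clump_cells=3, clump_diameter_um=(12, 16),
                             rng_seed=s, day=1) for s in range(4)]
        imgs = [render_dic(s) for s in scenes]
        table = build_feature_table([s.truth for s in scenes], imgs)
        res = assign_semantics(fit_kmeans(table), table)
        labels = res.semantic_labels()
        truth_pheno = []
        for scene in sorted(scenes, key=lambda s: s.image_id):
            truth_pheno += [scene.phenotypes[r] for r in sorted(scene.phenotypes)]
        truth_pheno = np.array(truth_pheno)
        fibers = truth_pheno == "fiber"
        # red should capture the majority of fibers, and vice versa
        assert (labels[fibers] == "red").mean() > 0.8
        assert (truth_pheno[labels == "red"] == "fiber").mean() > 0.8

    def test_requires_k3(self):
        res = ClusterResult(
            centroids=np.zeros((2, 6)), assignment=np.array([0, 1]), inertia=0.0
        )
        with pytest.raises(ParameterError):
            assign_semantics(res, pd.DataFrame())


class TestClusterShares:
    def test_reference_shares(self):
        out = cluster_shares({"blue": 4641, "red": 1320, "green": 119})
        shares = dict(zip(out.semantic_label, out.share_pct))
        assert shares == {"blue": 76.33, "red": 21.71, "green": 1.96}
        assert out["count"].sum() == 6080

    def test_zero_count_class(self):
        out = cluster_shares({"blue": 1, "red": 1, "green": 0})
        assert list(out.share_pct) == [50.0, 50.0, 0.0]

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            counts = {k: int(c) for k, c in zip("abc", rng.integers(0, 999, 3))}
            if sum(counts.values()) == 0:
                continue
            out = cluster_shares(counts)
            assert abs(out.share_pct.sum() - 100.0) <= 0.02

    def test_permutation_invariant(self):
        a = cluster_shares({"blue": 10, "red": 20, "green": 5})
        b = cluster_shares({"green": 5, "blue": 10, "red": 20})
        pd.testing.assert_frame_equal(
            a.sort_values("semantic_label").reset_index(drop=True),
            b.sort_values("semantic_label").reset_index(drop=True),
        )

    def test_all_zero_raises(self):
        with pytest.raises(ParameterError):
            cluster_shares({"blue": 0, "red": 0, "green": 0})


class TestIsomap:
    def test_line_embedding_preserves_order(self):
        t = np.linspace(0, 1, 50)
        rng = np.random.default_rng(0)
        direction = rng.standard_normal(6)
        X = np.outer(t, direction)
        emb = isomap_embed(X, n_neighbors=5, standardize=False)
        assert emb.shape == (50, 2)
        r = abs(np.corrcoef(emb[:, 0], t)[0, 1])
        assert r > 0.99

    def test_disconnected_graph_raises(self):
        X = np.zeros((20, 6))
        X[10:] += 100.0
        X += 0.01 * np.random.default_rng(1).standard_normal(X.shape)
        with pytest.raises(ParameterError, match="n_neighbors"):
            isomap_embed(X, n_neighbors=3, standardize=False)

    def test_blue_red_compact_green_dispersed(self):
        """Mirrors the verification plot: phenotype clusters are compact in
        the embedding while conglomerates scatter."""
        rng = np.random.default_rng(4)
        blue = rng.normal(0.0, 0.1, size=(80, 6))
        red = rng.normal(3.0, 0.1, size=(40, 6))
        green = rng.uniform(-4, 8, size=(10, 6))
        X = np.vstack([blue, red, green])
        emb = isomap_embed(X, n_neighbors=10, standardize=False)

        def dispersion(e):
            return np.linalg.norm(e - e.mean(0), axis=1).mean()

        assert dispersion(emb[:80]) < dispersion(emb[120:])
        assert dispersion(emb[80:120]) < dispersion(emb[120:])


class TestTimelineSummary:
    @staticmethod
    def simple_result(labels):
        k = 3
        lut = {"blue": 0, "red": 1, "green": 2}
        assignment = np.array([lut[l] for l in labels])
        return ClusterResult(
            centroids=np.zeros((k, 6)), assignment=assignment, inertia=0.0,
            semantic={0: "blue", 1: "red", 2: "green"},
        )

    def test_average_per_image(self):
        table = pd.DataFrame({
            "image_id": ["a"] * 3 + ["b"] * 5,
            "day": 1,
            "region_id": list(range(3)) + list(range(5)),
        })
        res = self.simple_result(["blue"] * 8)
        out = timeline_summary(res, table)
        blue = out[(out.day == 1) & (out.semantic_label == "blue")].iloc[0]
        assert blue.avg_regions_per_image == 4.0
        assert blue.n_images == 2
        green = out[(out.day == 1) & (out.semantic_label == "green")].iloc[0]
        assert green.avg_regions_per_image == 0.0

    def test_missing_day_raises(self):
        table = pd.DataFrame({"image_id": ["a"], "day": [np.nan], "region_id": [1]})
        res = self.simple_result(["blue"])
        with pytest.raises(ParameterError):
            timeline_summary(res, table)

    def test_programmed_day_schedule_recovered(self):
        """A 7-day series with programmed per-day convex counts: recovered
        averages stay within 15% of the programme (plus a one-cell floor for
        segmentation dropouts)."""
        from dic_cellscope.segmentation import segment_image

        programme = {1: 4, 2: 6, 3: 9, 4: 12, 5: 8, 6: 6, 7: 5}
        labs, imgs = [], []
        for day, n in programme.items():
            scene = make_scene(n, 0, shape=(448, 448), rng_seed=100 + day, day=day)
            img = render_dic(scene)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                labs.append(segment_image(img))
            imgs.append(img)
        table = build_feature_table(labs, imgs)
        res = ClusterResult(
            centroids=np.zeros((3, 6)),
            assignment=np.zeros(len(table), dtype=int),
            inertia=0.0,
            semantic={0: "blue", 1: "red", 2: "green"},
        )
        out = timeline_summary(res, table, images_per_day={d: 1 for d in programme})
        for day, n in programme.items():
            got = out[(out.day == day) & (out.semantic_label == "blue")]
            got = float(got.avg_regions_per_image.iloc[0])
            assert abs(got - n) <= max(0.15 * n, 1.0), (day, got, n)
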