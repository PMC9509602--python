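"""Closed-form diversity checks, ordination recovery and PERMANOVA behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from urotag.ecology import (
    chao1,
    distance_matrix,
    pcoa,
    permanova,
    shannon,
    simpson,
    venn_summary,
)


class TestAlphaDiversity:
    def test_chao1_no_singletons_equals_richness(self):
        assert chao1([5, 3, 2]) == 3.0

    def test_chao1_bias_corrected_formula(self):
        # S_obs=5, F1=2, F2=1: 5 + 2*1/(2*2) = 5.5
        assert chao1([5, 3, 1, 1, 2]) == 5.5

    def test_chao1_single_singleton(self):
        assert chao1([1]) == 1.0

    def test_chao1_lower_bounded_by_richness(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 10, size=15)
            if counts.sum() == 0:
                continue
            f1 = int((counts == 1).sum())
            est = chao1(counts)
            s_obs = int((counts > 0).sum())
            assert est >= s_obs
            if f1 <= 1:
                assert est == s_obs

    def test_chao1_undefined_on_empty(self):
        with pytest.raises(ValueError):
            chao1([0, 0])

    def test_shannon_uniform(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4))

    def test_shannon_single_species_zero(self):
        assert shannon([1.0]) == 0.0

    def test_shannon_closed_form(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2))

    def test_simpson_values(self):
        assert simpson([0.25] * 4) == pytest.approx(0.75)
        assert simpson([1.0]) == 0.0
        assert simpson([0.5, 0.5]) == pytest.approx(0.5)

    def test_negative_input_rejected(self):
        for fn in (shannon, simpson, chao1):
            with pytest.raises(ValueError):
                fn([-1, 2])


class TestDistances:
    @pytest.fixture
    def profiles(self, rng):
        mat = rng.dirichlet(np.ones(10), size=5).T
        return pd.DataFrame(mat, columns=[f"s{i}" for i in range(5)])

    def test_identical_samples_zero(self):
        df = pd.DataFrame({"a": [0.4, 0.6], "b": [0.4, 0.6]})
        for metric in ("bray_curtis", "jaccard_binary", "euclidean"):
            assert distance_matrix(df, metric)["a", "b"] == 0.0

    def test_disjoint_supports_max(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert distance_matrix(df, "bray_curtis")["a", "b"] == 1.0
        assert distance_matrix(df, "jaccard_binary")["a", "b"] == 1.0

    def test_bray_curtis_hand_example(self):
        df = pd.DataFrame({"x": [2, 1, 0], "y": [1, 1, 1]}, dtype=float)
        assert distance_matrix(df, "bray_curtis")["x", "y"] == pytest.approx(1 / 3)

    def test_metric_axioms_and_bounds(self, profiles):
        for metric in ("bray_curtis", "jaccard_binary", "euclidean"):
            d = np.asarray(distance_matrix(profiles, metric).data)
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert (d >= 0).all()
            if metric != "euclidean":
                assert (d <= 1 + 1e-12).all()

    def test_unknown_metric(self, profiles):
        with pytest.raises(ValueError):
            distance_matrix(profiles, "unifrac")


class TestPCoA:
    def test_recovers_euclidean_configuration(self, rng):
        points = rng.normal(size=(12, 3))
        d = squareform(pdist(points))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        res = pcoa(dm, n_axes=3)
        _, _, disparity = procrustes(points, res.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_matches_pca_eigenvalues(self, rng):
        points = rng.normal(size=(10, 4))
        centred = points - points.mean(axis=0)
        pca_eigs = np.sort(np.linalg.eigvalsh(centred.T @ centred))[::-1]
        dm = DistanceMatrix(squareform(pdist(points)), ids=[f"s{i}" for i in range(10)])
        res = pcoa(dm, n_axes=4)
        np.testing.assert_allclose(res.eigenvalues[:4], pca_eigs[:4], atol=1e-9)

    def test_identical_samples_coincide(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        np.testing.assert_allclose(
            res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-12
        )

    def test_equilateral_eigenstructure(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        positive = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1])

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcoa(
                type("FakeDM", (), {"data": np.array([[0, 1.0], [2.0, 0]]), "ids": ["a", "b"]})()
            )


class TestPermanova:
    @pytest.fixture
    def clouds(self, rng):
        a = rng.normal(0, 1, size=(8, 4))
        b = rng.normal(15, 1, size=(8, 4))
        pts = np.vstack([a, b])
        ids = [f"s{i}" for i in range(16)]
        labels = ["a"] * 8 + ["b"] * 8
        return DistanceMatrix(squareform(pdist(pts)), ids=ids), labels

    def test_separated_clouds_min_p(self, clouds):
        dm, labels = clouds
        _, p = permanova(dm, labels, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_statistic_invariant_to_sample_order(self, clouds, rng):
        dm, labels = clouds
        f1, _ = permanova(dm, labels, n_perm=9, seed=1)
        perm = rng.permutation(16)
        d2 = np.asarray(dm.data)[np.ix_(perm, perm)]
        dm2 = DistanceMatrix(d2, ids=[dm.ids[i] for i in perm])
        f2, _ = permanova(dm2, [labels[i] for i in perm], n_perm=9, seed=1)
        assert f1 == pytest.approx(f2)

    def test_matches_skbio_pseudo_f(self, rng):
        pts = rng.normal(size=(14, 5))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(14)])
        labels = ["a"] * 7 + ["b"] * 7
        f_ours, _ = permanova(dm, labels, n_perm=9, seed=0)
        res = skbio_permanova(dm, grouping=labels, permutations=9)
        assert f_ours == pytest.approx(float(res["test statistic"]), rel=1e-9)

    def test_strata_respect_pairing(self, rng):
        pts = rng.normal(size=(12, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(12)])
        labels = ["a", "b"] * 6
        strata = [f"subj{i // 2}" for i in range(12)]
        f, p = permanova(dm, labels, n_perm=99, strata=strata, seed=3)
        assert 0 < p <= 1

    def test_singleton_group_rejected(self, rng):
        pts = rng.normal(size=(5, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcde"))
        with pytest.raises(ValueError):
            permanova(dm, ["x", "x", "x", "x", "y"], n_perm=9)


class TestVenn:
    def test_identical_sets_fully_shared(self):
        v = venn_summary({"a", "b"}, {"a", "b"})
        assert v.pct_shared == 100.0 and v.n_only_a == v.n_only_b == 0

    def test_disjoint_small_sets(self):
        v = venn_summary({"a", "b"}, {"c", "d", "e"})
        assert (v.pct_shared, v.pct_only_a, v.pct_only_b) == (0.0, 40.0, 60.0)

    def test_study_partition_percentages(self):
        """181 shared / 77 stone-only / 193 non-stone-only over a union of 451."""
        v = venn_summary(
            {f"sh{i}" for i in range(181)} | {f"a{i}" for i in range(77)},
            {f"sh{i}" for i in range(181)} | {f"b{i}" for i in range(193)},
        )
        assert v.n_union == 451
        assert (v.pct_shared, v.pct_only_a, v.pct_only_b) == (40.13, 17.07, 42.79)
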