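"""Community statistics: closed forms, oracles and cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from lowbiom.community import (
    CommunityError,
    DistanceMatrix,
    bray_curtis,
    paired_spearman,
    pcoa,
    permanova,
    permdisp,
    relative_abundance,
    select_shared_features,
    shannon,
    shannon_per_sample,
)
from lowbiom.io_formats import FeatureTable, TaxonomyMap, aggregate_by_rank

from .conftest import random_table


def euclidean_dm(points: np.ndarray) -> DistanceMatrix:
    ids = [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)))


class TestRelativeAbundance:
    def test_proportions(self):
        t = FeatureTable(np.array([[2], [3], [5]]), ["a", "b", "c"], ["s"])
        props = relative_abundance(t)
        assert props["s"].tolist() == [0.2, 0.3, 0.5]

    def test_zero_depth_sample_named(self):
        t = FeatureTable(np.array([[0], [0]]), ["a", "b"], ["empty_one"])
        with pytest.raises(CommunityError, match="empty_one"):
            relative_abundance(t)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, sparsity=0.2)
        keep = [s for s in t.sample_ids if t.depth(s) > 0]
        props = relative_abundance(t.filter_samples(keep))
        assert np.allclose(props.sum(axis=0), 1.0)


class TestShannon:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.25] * 4, np.log(4)),
            ([1.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5 * np.log(2)),
        ],
    )
    def test_closed_forms(self, p, expected):
        assert shannon(p) == pytest.approx(expected)

    def test_negative_entry_rejected(self):
        with pytest.raises(CommunityError):
            shannon([1.2, -0.2])

    def test_aggregation_never_increases_entropy(self, simple_taxonomy):
        rng = np.random.default_rng(3)
        t = random_table(rng, n_features=3, sparsity=0.1)
        keep = [s for s in t.sample_ids if t.depth(s) > 0]
        t = t.filter_samples(keep)
        agg = aggregate_by_rank(t, simple_taxonomy, "genus")
        before = shannon_per_sample(t)
        after = shannon_per_sample(agg)
        assert (after <= before + 1e-12).all()


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        df = pd.DataFrame({"a": [0.2, 0.8], "b": [0.2, 0.8]})
        dm = bray_curtis(df)
        assert dm.d[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert bray_curtis(df).d[0, 1] == pytest.approx(1.0)

    def test_half_overlap(self):
        df = pd.DataFrame({"x": [0.5, 0.5, 0.0], "y": [0.0, 0.5, 0.5]})
        assert bray_curtis(df).d[0, 1] == pytest.approx(0.5)

    def test_bounded_and_reflexive_on_random_tables(self):
        rng = np.random.default_rng(8)
        t = random_table(rng, sparsity=0.2)
        keep = [s for s in t.sample_ids if t.depth(s) > 0]
        dm = bray_curtis(t.filter_samples(keep))
        assert np.all(dm.d >= 0) and np.all(dm.d <= 1 + 1e-12)
        assert np.allclose(np.diag(dm.d), 0)

    def test_formula_direct(self):
        # hand evaluation of 1 - 2*sum(min)/(sum x + sum y) on counts
        df = pd.DataFrame({"x": [6.0, 2.0], "y": [2.0, 4.0]})
        expected = 1 - 2 * (2 + 2) / (8 + 6)
        assert bray_curtis(df).d[0, 1] == pytest.approx(expected)


class TestPcoa:
    def test_collinear_points_axis1(self):
        pts = np.array([[0.0], [3.0], [7.0]])
        res = pcoa(euclidean_dm(pts))
        ax1 = res.coordinates[:, 0]
        d_rec = np.abs(ax1[:, None] - ax1[None, :])
        assert np.allclose(d_rec, squareform(pdist(pts)), atol=1e-8)

    def test_euclidean_cloud_distances_recovered(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 4))
        dm = euclidean_dm(pts)
        res = pcoa(dm)
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, dm.d, atol=1e-8)

    def test_duplicate_samples_identical_coordinates(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [3.0, 0.0]])
        res = pcoa(euclidean_dm(pts))
        assert np.allclose(res.coordinates[1], res.coordinates[2], atol=1e-8)

    def test_eigenvalues_positive_descending_proportions(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 3))
        res = pcoa(euclidean_dm(pts))
        assert np.all(res.eigenvalues > 0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(CommunityError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        t = random_table(rng, n_features=15, n_samples=8, sparsity=0.2)
        keep = [s for s in t.sample_ids if t.depth(s) > 0]
        dm = bray_curtis(t.filter_samples(keep))
        ours = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.d, ids=dm.sample_ids)
        )
        k = len(ours.eigenvalues)
        assert np.allclose(
            ref.eigvals.to_numpy()[:k], ours.eigenvalues, atol=1e-8
        )
        # coordinates agree up to per-axis sign
        for j in range(min(3, k)):
            ref_ax = ref.samples.to_numpy()[:, j]
            assert np.allclose(ref_ax, ours.coordinates[:, j], atol=1e-6) or \
                np.allclose(ref_ax, -ours.coordinates[:, j], atol=1e-6)


class TestPermanova:
    def test_exhaustive_enumeration_3v3(self):
        """Exact p on n=6 by full 20-arrangement enumeration, checked
        against an independent brute-force oracle."""
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2.5, 1, (3, 2))])
        dm = euclidean_dm(pts)
        labels = ["g1"] * 3 + ["g2"] * 3
        res = permanova(dm, labels, exhaustive=True)
        assert res.n_permutations == 20

        # oracle: recompute F for every label arrangement from the raw formula
        import itertools

        d2 = dm.d**2
        n = 6

        def f_of(lab):
            ss_tot = d2.sum() / (2 * n)
            ss_w = 0.0
            for g in set(lab):
                idx = [i for i, l in enumerate(lab) if l == g]
                ss_w += sum(
                    d2[i, j] for i in idx for j in idx if i < j
                ) / len(idx)
            return ((ss_tot - ss_w) / 1) / (ss_w / (n - 2))

        f_obs = f_of(labels)
        arrangements = set(itertools.permutations(labels))
        hits = sum(1 for a in arrangements if f_of(list(a)) >= f_obs - 1e-12)
        assert res.p_value == pytest.approx(hits / len(arrangements))
        assert res.pseudo_f == pytest.approx(f_obs)

    def test_monte_carlo_approaches_enumeration(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(1.5, 1, (3, 2))])
        dm = euclidean_dm(pts)
        labels = ["a"] * 3 + ["b"] * 3
        exact = permanova(dm, labels, exhaustive=True)
        mc = permanova(dm, labels, n_perm=20000, seed=1)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_separated_clusters_minimal_p(self):
        rng = np.random.default_rng(6)
        pts = np.vstack(
            [rng.normal(0, 0.05, (15, 2)), rng.normal(50, 0.05, (15, 2))]
        )
        dm = euclidean_dm(pts)
        labels = ["a"] * 15 + ["b"] * 15
        res = permanova(dm, labels, n_perm=9999, seed=0)
        assert res.p_value == pytest.approx(1 / 10000)
        assert res.r_squared > 0.95

    def test_r_squared_decomposition(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 3))
        dm = euclidean_dm(pts)
        labels = ["a"] * 5 + ["b"] * 5
        res = permanova(dm, labels, n_perm=99, seed=0)
        assert 0 <= res.r_squared <= 1
        assert res.p_value >= 1 / 100

    def test_degenerate_all_zero_distances(self):
        dm = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        res = permanova(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.pseudo_f == 0.0 and res.p_value == 1.0

    def test_fewer_samples_than_groups_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(CommunityError):
            permanova(dm, ["g1", "g2"], n_perm=9, seed=0)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(13)
        pts = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(1, 1, (6, 3))])
        dm = euclidean_dm(pts)
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(dm, labels, n_perm=999, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.d, ids=dm.sample_ids),
            grouping=labels,
            permutations=999,
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)
        assert ours.p_value == pytest.approx(ref["p-value"], abs=0.05)


class TestPermdisp:
    def test_mirror_groups_equal_dispersion(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (8, 2))
        pts = np.vstack([a, a + 100.0])  # same shape, far apart
        dm = euclidean_dm(pts)
        labels = ["a"] * 8 + ["b"] * 8
        res = permdisp(dm, labels, n_perm=499, seed=0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value > 0.5

    def test_tight_vs_diffuse_detected(self):
        rng = np.random.default_rng(14)
        pts = np.vstack(
            [rng.normal(0, 0.05, (12, 2)), rng.normal(0, 3.0, (12, 2))]
        )
        dm = euclidean_dm(pts)
        labels = ["tight"] * 12 + ["diffuse"] * 12
        res = permdisp(dm, labels, n_perm=999, seed=0)
        assert res.p_value <= 0.05
        assert res.group_mean_distance["diffuse"] > res.group_mean_distance["tight"]

    def test_single_member_group_rejected(self):
        rng = np.random.default_rng(1)
        dm = euclidean_dm(rng.normal(size=(4, 2)))
        with pytest.raises(CommunityError):
            permdisp(dm, ["a", "b", "b", "b"], n_perm=9, seed=0)


class TestSharedFeatures:
    def _tables(self, totals_a, totals_b):
        fids = [f"f{i}" for i in range(len(totals_a))]
        ta = FeatureTable(np.array(totals_a)[:, None], fids, ["a1"])
        tb = FeatureTable(np.array(totals_b)[:, None], fids, ["b1"])
        return ta, tb

    def test_strict_threshold(self):
        ta, tb = self._tables([60, 60], [40, 41])
        assert select_shared_features(ta, tb, min_total=100) == ["f1"]

    def test_all_below_threshold_empty(self):
        ta, tb = self._tables([1, 2], [3, 4])
        assert select_shared_features(ta, tb, min_total=100) == []

    def test_threshold_zero_keeps_present_features(self):
        ta, tb = self._tables([1, 0], [0, 0])
        assert select_shared_features(ta, tb, min_total=0) == ["f0"]

    def test_per_sample_mode(self):
        fids = ["f0", "f1"]
        ta = FeatureTable(np.array([[150, 150], [150, 99]]), fids, ["a1", "a2"])
        tb = FeatureTable(np.array([[120, 130], [500, 500]]), fids, ["b1", "b2"])
        assert select_shared_features(ta, tb, min_total=100, per_sample=True) == ["f0"]

    def test_disjoint_feature_spaces_warn(self):
        ta = FeatureTable(np.array([[1]]), ["x"], ["a1"])
        tb = FeatureTable(np.array([[1]]), ["y"], ["b1"])
        with pytest.warns(UserWarning):
            assert select_shared_features(ta, tb) == []


class TestPairedSpearman:
    def _pair_tables(self, va, vb):
        fids = [f"f{i}" for i in range(len(va))]
        ta = FeatureTable(np.array(va)[:, None], fids, ["mec1"])
        tb = FeatureTable(np.array(vb)[:, None], fids, ["amn1"])
        return ta, tb, {"pair1": ("mec1", "amn1")}, fids

    def test_monotone_pair_rho_one(self):
        ta, tb, pairs, fids = self._pair_tables([1, 5, 9, 20], [2, 6, 11, 30])
        corrs, avg = paired_spearman(ta, tb, pairs, fids)
        assert corrs[0].rho == pytest.approx(1.0)
        assert avg == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        ta, tb, pairs, fids = self._pair_tables([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        corrs, _ = paired_spearman(ta, tb, pairs, fids)
        assert corrs[0].rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        ta, tb, pairs, fids = self._pair_tables([1, 2, 3, 4], [1, 3, 2, 4])
        corrs, _ = paired_spearman(ta, tb, pairs, fids)
        assert corrs[0].rho == pytest.approx(0.8)

    def test_exact_permutation_p_small_k(self):
        # k=4 features -> exact p over 4! = 24 permutations
        ta, tb, pairs, fids = self._pair_tables([1, 2, 3, 4], [1, 2, 3, 4])
        corrs, _ = paired_spearman(ta, tb, pairs, fids)
        # only the 2 fully monotone orderings reach |rho| = 1
        assert corrs[0].p_raw == pytest.approx(2 / 24)

    def test_constant_vector_flagged_and_excluded(self):
        fids = ["f0", "f1", "f2"]
        ta = FeatureTable(
            np.array([[5, 1], [5, 2], [5, 3]]), fids, ["a1", "a2"]
        )
        tb = FeatureTable(
            np.array([[1, 1], [2, 2], [3, 3]]), fids, ["b1", "b2"]
        )
        pairs = {"p1": ("a1", "b1"), "p2": ("a2", "b2")}
        corrs, avg = paired_spearman(ta, tb, pairs, fids)
        by_id = {c.pair_id: c for c in corrs}
        assert by_id["p1"].rho is None
        assert by_id["p2"].rho == pytest.approx(1.0)
        assert avg == pytest.approx(1.0)

    def test_bonferroni_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(4)
        fids = [f"f{i}" for i in range(12)]
        n_pairs = 5
        ta = FeatureTable(rng.integers(0, 100, (12, n_pairs)), fids,
                          [f"a{i}" for i in range(n_pairs)])
        tb = FeatureTable(rng.integers(0, 100, (12, n_pairs)), fids,
                          [f"b{i}" for i in range(n_pairs)])
        pairs = {f"p{i}": (f"a{i}", f"b{i}") for i in range(n_pairs)}
        corrs, _ = paired_spearman(ta, tb, pairs, fids)
        for c in corrs:
            assert c.p_bonferroni >= c.p_raw
            assert c.p_bonferroni == pytest.approx(min(1.0, n_pairs * c.p_raw))
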