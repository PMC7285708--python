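from itertools import permutations as iter_perms

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from tailvirkit.stats import (DistanceMatrix, anosim, bray_curtis, euclidean,
                              mantel, pca, pcoa, pearson, permanova, standardize)


def _dm(points, metric="euclidean"):
    pts = np.asarray(points, dtype=float)
    ids = [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(ids, squareform(pdist(pts, metric=metric)), metric)


# ---------------------------------------------------------------------------
# naive first-principles oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def naive_anosim_r(d, labels):
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = sps.rankdata([d[i, j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    return (np.mean(between) - np.mean(within)) / (len(pairs) / 2)


def naive_permanova_f(d, labels):
    n = len(labels)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    g_count = len(set(labels))
    return ((ss_total - ss_within) / (g_count - 1)) / (ss_within / (n - g_count))


def exhaustive_p(d, labels, stat_fn):
    observed = stat_fn(d, labels)
    seen, hits, total = set(), 0, 0
    for perm in iter_perms(range(len(labels))):
        lab = tuple(labels[i] for i in perm)
        if lab in seen:
            continue
        seen.add(lab)
        total += 1
        if stat_fn(d, lab) >= observed - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# distances & standardization
# ---------------------------------------------------------------------------

class TestDistances:
    def test_bray_curtis_identical_disjoint_and_hand_value(self):
        table = pd.DataFrame([[1, 2], [1, 2], [0, 5], [2, 1]],
                             index=list("abcd"), columns=["t1", "t2"])
        dm = bray_curtis(table)
        assert dm.d[0, 1] == 0.0
        disjoint = bray_curtis(pd.DataFrame([[3, 0], [0, 7]], index=["a", "b"]))
        assert disjoint.d[0, 1] == 1.0
        # x=(1,2), y=(2,1): (1+1)/(3+3) = 1/3
        third = bray_curtis(pd.DataFrame([[1, 2], [2, 1]], index=["a", "b"]))
        assert third.d[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_sample_errors_by_name(self):
        with pytest.raises(ValueError, match="zz"):
            bray_curtis(pd.DataFrame([[1, 2], [0, 0]], index=["ok", "zz"]))

    def test_standardize_zscores_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(5, 3, size=(8, 3)), columns=list("xyz"))
        z = standardize(table)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-12)
        z2 = standardize(table.assign(x=table["x"] * 7 - 3))
        assert np.allclose(z["x"], z2["x"])
        assert list(standardize(pd.DataFrame({"a": [1, 2, 3]}))["a"]) == \
            pytest.approx([-1, 0, 1])

    def test_constant_column_dropped_with_warning(self):
        table = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 4, 4]})
        with pytest.warns(UserWarning, match="b"):
            z = standardize(table)
        assert list(z.columns) == ["a"]


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

class TestOrdination:
    def test_pcoa_recovers_points_on_a_line(self):
        xs = np.array([0.0, 1.0, 3.0, 7.0, 10.0])
        dm = _dm([[x] for x in xs])
        res = pcoa(dm)
        r = np.corrcoef(res.coordinates["PCo1"], xs)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_pcoa_of_euclidean_equals_pca_scores(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(7, 4)), index=[f"s{i}" for i in range(7)])
        res_pcoa = pcoa(_dm(table.values))
        res_pca = pca(table, n_axes=3)
        for ax in range(3):
            a = res_pcoa.coordinates.iloc[:, ax]
            b = res_pca.coordinates.iloc[:, ax]
            assert abs(np.corrcoef(a, b)[0, 1]) == pytest.approx(1.0, abs=1e-6)

    def test_two_samples_single_axis_distance(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 2.5], [2.5, 0]]), "euclidean")
        res = pcoa(dm)
        coords = res.coordinates.iloc[:, 0]
        assert abs(coords["a"] - coords["b"]) == pytest.approx(2.5)

    def test_pcoa_matches_scikit_bio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        import skbio
        rng = np.random.default_rng(3)
        table = rng.lognormal(size=(6, 10))
        d = squareform(pdist(table, metric="braycurtis"))
        ids = [f"s{i}" for i in range(6)]
        mine = pcoa(DistanceMatrix(ids, d, "bray_curtis"))
        theirs = skbio_ord.pcoa(skbio.DistanceMatrix(d, ids))
        np.testing.assert_allclose(
            np.abs(mine.coordinates.values[:, :2]),
            np.abs(theirs.samples.values[:, :2]), atol=1e-8)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

class TestAnosim:
    def test_perfect_separation_r_one(self):
        dm = _dm([[0], [0.1], [10], [10.1]])
        groups = pd.Series({"s0": "a", "s1": "a", "s2": "b", "s3": "b"})
        r, _ = anosim(dm, groups, permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_null_labels_r_centred_on_zero(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(30):
            dm = _dm(rng.normal(size=(8, 3)))
            labels = pd.Series(rng.permutation(["a"] * 4 + ["b"] * 4),
                               index=dm.sample_ids)
            rs.append(anosim(dm, labels, permutations=9, seed=0)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_exhaustive_p_matches_independent_enumeration(self):
        rng = np.random.default_rng(6)
        dm = _dm(rng.normal(size=(6, 2)))
        labels = pd.Series(["a", "a", "a", "b", "b", "b"], index=dm.sample_ids)
        r, p = anosim(dm, labels, method="exhaustive")
        assert r == pytest.approx(naive_anosim_r(dm.d, list(labels)))
        assert p == pytest.approx(exhaustive_p(dm.d, list(labels), naive_anosim_r))

    def test_matches_scikit_bio_statistic(self):
        sk = pytest.importorskip("skbio.stats.distance")
        import skbio
        rng = np.random.default_rng(7)
        dm = _dm(rng.normal(size=(9, 3)))
        labels = ["a"] * 4 + ["b"] * 5
        mine, _ = anosim(dm, pd.Series(labels, index=dm.sample_ids),
                         permutations=99, seed=0)
        theirs = sk.anosim(skbio.DistanceMatrix(dm.d, dm.sample_ids),
                           np.array(labels), permutations=0)
        assert mine == pytest.approx(theirs["test statistic"])

    def test_single_group_errors(self):
        dm = _dm([[0], [1], [2]])
        with pytest.raises(ValueError):
            anosim(dm, pd.Series("a", index=dm.sample_ids))


class TestPermanova:
    def test_identical_replicates_r2_one(self):
        dm = _dm([[0], [0], [5], [5]])
        groups = pd.Series({"s0": "a", "s1": "a", "s2": "b", "s3": "b"})
        _, r2, _ = permanova(dm, groups, permutations=49, seed=0)
        assert r2 == pytest.approx(1.0)

    def test_null_r2_near_expected_value(self):
        # random labels: E[R^2] ~ (g-1)/(n-1)
        rng = np.random.default_rng(8)
        r2s = []
        for _ in range(60):
            dm = _dm(rng.normal(size=(8, 3)))
            labels = pd.Series(rng.permutation(["a"] * 4 + ["b"] * 4),
                               index=dm.sample_ids)
            r2s.append(permanova(dm, labels, permutations=9, seed=0)[1])
        assert np.mean(r2s) == pytest.approx(1 / 7, abs=0.03)

    def test_exhaustive_p_matches_independent_enumeration(self):
        rng = np.random.default_rng(9)
        dm = _dm(rng.normal(size=(6, 2)))
        labels = pd.Series(["a", "a", "b", "b", "b", "b"], index=dm.sample_ids)
        f, _, p = permanova(dm, labels, method="exhaustive")
        assert f == pytest.approx(naive_permanova_f(dm.d, list(labels)))
        assert p == pytest.approx(exhaustive_p(dm.d, list(labels), naive_permanova_f))

    def test_matches_scikit_bio_pseudo_f(self):
        sk = pytest.importorskip("skbio.stats.distance")
        import skbio
        rng = np.random.default_rng(10)
        dm = _dm(rng.normal(size=(9, 3)))
        labels = ["a"] * 4 + ["b"] * 5
        f, r2, _ = permanova(dm, pd.Series(labels, index=dm.sample_ids),
                             permutations=99, seed=0)
        theirs = sk.permanova(skbio.DistanceMatrix(dm.d, dm.sample_ids),
                              np.array(labels), permutations=0)
        assert f == pytest.approx(theirs["test statistic"])


class TestMantel:
    def test_identity_and_affine_invariance(self):
        rng = np.random.default_rng(11)
        d1 = _dm(rng.normal(size=(7, 3)))
        r, _ = mantel(d1, d1, permutations=9, seed=0)
        assert r == pytest.approx(1.0)
        d2 = DistanceMatrix(d1.sample_ids, 3.0 * d1.d + 0.5 * (1 - np.eye(7)),
                            "euclidean")
        r2, _ = mantel(d1, d2, permutations=9, seed=0)
        assert r2 == pytest.approx(1.0)

    def test_exhaustive_p_at_n5_matches_enumeration(self):
        rng = np.random.default_rng(12)
        d1 = _dm(rng.normal(size=(5, 2)))
        d2 = _dm(rng.normal(size=(5, 2)))
        r, p = mantel(d1, d2, method="exhaustive")
        iu = np.triu_indices(5, k=1)
        v1 = d1.d[iu]
        hits = total = 0
        for perm in iter_perms(range(5)):
            dp = d2.d[np.ix_(perm, perm)]
            total += 1
            if sps.pearsonr(v1, dp[iu]).statistic >= r - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / total)

    def test_matches_scikit_bio(self):
        sk = pytest.importorskip("skbio.stats.distance")
        import skbio
        rng = np.random.default_rng(13)
        d1 = _dm(rng.normal(size=(8, 3)))
        d2 = _dm(rng.normal(size=(8, 3)))
        mine_r, _ = mantel(d1, d2, permutations=99, seed=0)
        theirs_r, _, _ = sk.mantel(skbio.DistanceMatrix(d1.d, d1.sample_ids),
                                   skbio.DistanceMatrix(d2.d, d2.sample_ids),
                                   permutations=0)
        assert mine_r == pytest.approx(theirs_r)

    def test_mismatched_samples_error(self):
        d1 = _dm([[0], [1], [2]])
        d2 = DistanceMatrix(["x", "y", "z"], d1.d, "euclidean")
        with pytest.raises(ValueError):
            mantel(d1, d2)


class TestPearson:
    def test_perfect_linear_and_hand_value(self):
        r, p = pearson([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        r2, _ = pearson([1, 2, 3], [1, 2, 2])
        assert r2 == pytest.approx(0.8660, abs=1e-4)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


def test_permutation_pvalues_never_zero_and_reproducible():
    rng = np.random.default_rng(14)
    dm = _dm(np.vstack([rng.normal(0, 0.1, size=(4, 2)),
                        rng.normal(5, 0.1, size=(4, 2))]))
    groups = pd.Series(["a"] * 4 + ["b"] * 4, index=dm.sample_ids)
    r1 = anosim(dm, groups, permutations=99, seed=5)
    r2 = anosim(dm, groups, permutations=99, seed=5)
    assert r1 == r2
    assert r1[1] >= 1 / 100
    assert -1 <= r1[0] <= 1
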