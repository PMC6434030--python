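import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from biofilm_assembly.ordination import (
    PCoA,
    n_distinct_arrangements,
    pcoa,
    permanova,
)


def _brute_force_permanova(dm, labels):
    """Independent oracle: enumerate every label permutation explicitly and
    compute the pseudo-F from scratch with plain loops."""
    labels = list(labels)
    n = len(labels)
    values = sorted(set(labels))
    a = len(values)

    def f_stat(lab):
        ss_total = sum(dm[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for v in values:
            idx = [i for i, l in enumerate(lab) if l == v]
            ss = sum(
                dm[i][j] ** 2 for i in idx for j in idx if i < j
            )
            ss_within += ss / len(idx)
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    f_obs = f_stat(labels)
    seen = set()
    count = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if f_stat(perm) >= f_obs - 1e-12:
            count += 1
    return f_obs, count / total, total


class TestPermanova:
    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 2))
        X[4:] += 1.0
        dm = squareform(pdist(X))
        labels = ["g1"] * 4 + ["g2"] * 4
        res = permanova(dm, labels, n_perm=999, seed=0)
        f_oracle, p_oracle, total = _brute_force_permanova(dm, labels)
        assert res.exhaustive and res.n_permutations == total == 70
        assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=0)

    def test_strong_separation_attains_minimal_p(self):
        # within distances small, between large: only the two arrangements
        # equivalent to the observed split reach the observed F
        n1 = 3
        dm = np.full((6, 6), 1.0)
        np.fill_diagonal(dm, 0.0)
        for i, j in itertools.combinations(range(3), 2):
            dm[i, j] = dm[j, i] = 0.1
            dm[i + 3, j + 3] = dm[j + 3, i + 3] = 0.1
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova(dm, labels, n_perm=999, seed=0)
        assert res.exhaustive
        assert res.p_value == pytest.approx(2 / 20)
        assert res.r_squared > 0.8

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 3))
        dm = squareform(pdist(X))
        labels = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        res = permanova(dm, labels, n_perm=999, seed=1)
        order = rng.permutation(8)
        res2 = permanova(dm[np.ix_(order, order)], labels[order], n_perm=999, seed=1)
        assert res2.pseudo_F == pytest.approx(res.pseudo_F, rel=1e-12)
        assert res2.r_squared == pytest.approx(res.r_squared, rel=1e-12)
        assert res2.p_value == res.p_value  # exhaustive: exact equality

    def test_statistic_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(14, 3))
        X[7:] += 0.8
        dm = squareform(pdist(X))
        labels = ["a"] * 7 + ["b"] * 7
        mine = permanova(dm, labels, n_perm=99, seed=1)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm), grouping=labels, permutations=0
        )
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_three_groups_supported(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 2))
        dm = squareform(pdist(X))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(dm, labels, n_perm=200, seed=0)
        assert 0 < res.p_value <= 1
        assert n_distinct_arrangements(labels) == 1680

    def test_errors(self):
        dm = squareform(pdist(np.random.default_rng(0).normal(size=(4, 2))))
        with pytest.raises(ValueError, match="single sample"):
            permanova(dm, ["a", "a", "a", "b"], n_perm=10, seed=0)
        with pytest.raises(ValueError, match=">= 2 groups"):
            permanova(dm, ["a"] * 4, n_perm=10, seed=0)


class TestPCoA:
    def test_equilateral_simplex(self):
        dm = np.ones((3, 3)) - np.eye(3)
        res = pcoa(dm, n_axes=2)
        lam = res.eigenvalues
        assert lam[0] == pytest.approx(lam[1], rel=1e-9)
        coords = res.coordinates.to_numpy()
        rec = squareform(pdist(coords))
        np.testing.assert_allclose(rec[np.triu_indices(3, 1)], 1.0, atol=1e-9)

    def test_duplicate_sample_coincides(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 2))
        X = np.vstack([X, X[0]])  # duplicate the first point
        dm = squareform(pdist(X))
        res = pcoa(dm, n_axes=2)
        c = res.coordinates.to_numpy()
        np.testing.assert_allclose(c[0], c[-1], atol=1e-9)

    def test_euclidean_exactness(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(7, 3))
        dm = squareform(pdist(X))
        res = pcoa(dm, n_axes=6)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, dm, atol=1e-8)
        assert len(res.negative_eigenvalues) == 0

    def test_coordinates_centered_and_eigs_sorted(self):
        rng = np.random.default_rng(3)
        dm = squareform(pdist(rng.normal(size=(8, 4))))
        res = pcoa(dm, n_axes=3)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-10)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa

        rng = np.random.default_rng(5)
        dm = squareform(pdist(rng.normal(size=(9, 3))))
        mine = PCoA(n_components=4).fit(dm)
        ref = sk_pcoa(skbio.DistanceMatrix(dm))
        np.testing.assert_allclose(
            mine.eigenvalues_[:4], ref.eigvals.values[:4], atol=1e-9
        )
        k = mine.coordinates_.shape[1]  # only positive eigenvalues kept
        np.testing.assert_allclose(
            np.abs(mine.coordinates_.to_numpy()),
            np.abs(ref.samples.values[:, :k]),
            atol=1e-8,
        )

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            res = pcoa(np.zeros((4, 4)), n_axes=2)
        assert (res.coordinates.to_numpy() == 0).all()
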