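from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from crossfmt import FeatureTable, pca, pcoa, permanova, procrustes_mc
from crossfmt.multivariate import Ordination


def dm_from_points(points):
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.linalg.norm(points[i] - points[j])
    return DistanceMatrix(d, [f"s{i}" for i in range(n)])


class TestPcoa:
    def test_three_equidistant_points_two_equal_eigenvalues(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            ["a", "b", "c"])
        ordination = pcoa(dm)
        positive = ordination.eigenvalues[ordination.eigenvalues > 1e-10]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1])

    def test_recovers_line_embedding(self):
        dm = dm_from_points([[0.0], [1.0], [3.0], [6.0]])
        ordination = pcoa(dm)
        positive = ordination.eigenvalues[ordination.eigenvalues > 1e-8]
        assert len(positive) == 1
        axis = ordination.coordinates[:, 0]
        spacings = np.abs(np.diff(axis))
        np.testing.assert_allclose(spacings, [1, 2, 3], atol=1e-8)

    def test_euclidean_embedding_distances_recovered(self, rng):
        points = rng.normal(size=(7, 3))
        dm = dm_from_points(points)
        ordination = pcoa(dm)
        recovered = dm_from_points(ordination.coordinates)
        np.testing.assert_allclose(recovered.data, dm.data, atol=1e-8)

    def test_zero_matrix_gives_zero_coordinates(self):
        dm = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        ordination = pcoa(dm)
        np.testing.assert_allclose(ordination.coordinates, 0.0)

    def test_agrees_with_skbio_oracle(self, rng):
        points = rng.normal(size=(6, 2))
        dm = dm_from_points(points)
        ours = pcoa(dm)
        theirs = skbio_pcoa(dm, number_of_dimensions=2)
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[:2]), np.sort(theirs.eigvals.values[:2]),
            atol=1e-8)
        # coordinates agree up to per-axis sign
        ours2 = ours.coordinates[:, :2]
        theirs2 = theirs.samples.values[:, :2]
        for axis in range(2):
            assert (np.allclose(ours2[:, axis], theirs2[:, axis], atol=1e-6)
                    or np.allclose(ours2[:, axis], -theirs2[:, axis], atol=1e-6))


class TestPca:
    def _table(self, values):
        return FeatureTable(pd.DataFrame(
            values, index=[f"s{i}" for i in range(len(values))],
            columns=[f"k{j}" for j in range(len(values[0]))]), kind="ko")

    def test_duplicated_samples_collapse(self):
        table = self._table([[1.0, 2.0], [1.0, 2.0], [3.0, 1.0]])
        ordination = pca(table)
        np.testing.assert_allclose(ordination.coordinates[0],
                                   ordination.coordinates[1], atol=1e-10)

    def test_known_principal_axis(self):
        # points along y = 2x: first axis carries all variance
        table = self._table([[0, 0], [1, 2], [2, 4], [3, 6]])
        ordination = pca(table)
        assert ordination.proportion_explained[0] == pytest.approx(1.0)
        assert len(ordination.eigenvalues[ordination.eigenvalues > 1e-10]) == 1

    def test_total_variance_preserved(self, rng):
        values = rng.normal(size=(8, 5))
        table = self._table(np.abs(values))
        ordination = pca(table)
        x = np.abs(values)
        total_var = ((x - x.mean(axis=0)) ** 2).sum() / (len(x) - 1)
        assert ordination.eigenvalues.sum() == pytest.approx(total_var)


def brute_force_permanova_p(dm, labels):
    """Independent exhaustive oracle: all label arrangements via itertools."""
    from crossfmt.multivariate import _pseudo_f

    uniq, codes = np.unique(labels, return_inverse=True)
    d2 = np.asarray(dm.data) ** 2
    f_obs = _pseudo_f(d2, codes, uniq.size)
    f_all = []
    seen = set()
    for perm in permutations(codes.tolist()):
        if perm in seen:
            continue
        seen.add(perm)
        f_all.append(_pseudo_f(d2, np.asarray(perm), uniq.size))
    f_all = np.asarray(f_all)
    return (f_all >= f_obs - 1e-12).sum() / f_all.size


class TestPermanova:
    def test_exact_mode_matches_exhaustive_oracle(self, rng):
        for n_a, n_b in [(3, 3), (4, 3), (3, 4)]:
            points = rng.normal(size=(n_a + n_b, 2))
            points[:n_a] += [1.5, 0]
            dm = dm_from_points(points)
            labels = ["g1"] * n_a + ["g2"] * n_b
            res = permanova(dm, dict(zip(dm.ids, labels)), n_permutations="exact")
            oracle = brute_force_permanova_p(dm, labels)
            assert res.p == pytest.approx(oracle, abs=1e-12)

    def test_exact_mode_three_groups(self, rng):
        points = rng.normal(size=(9, 2))
        dm = dm_from_points(points)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(dm, labels, n_permutations="exact")
        assert res.p == pytest.approx(brute_force_permanova_p(dm, labels),
                                      abs=1e-12)

    def test_f_statistic_matches_skbio(self, rng):
        points = rng.normal(size=(10, 3))
        points[:5] += 1.0
        dm = dm_from_points(points)
        labels = pd.Series(["x"] * 5 + ["y"] * 5, index=dm.ids)
        ours = permanova(dm, labels, n_permutations=99, seed=0)
        theirs = skbio_permanova(dm, labels.values, permutations=99)
        assert ours.F == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_null_p_values_are_calibrated(self, rng):
        # exchangeable data: p should be roughly uniform; check the mean
        ps = []
        for _ in range(100):
            points = rng.normal(size=(8, 2))
            dm = dm_from_points(points)
            res = permanova(dm, ["a"] * 4 + ["b"] * 4, n_permutations="exact")
            ps.append(res.p)
        assert 0.35 < np.mean(ps) < 0.65
        assert min(ps) >= 1 / 70  # attainable grid bound, C(8,4)=70

    def test_degenerate_identical_coordinates(self):
        dm = DistanceMatrix(np.zeros((6, 6)), [f"s{i}" for i in range(6)])
        res = permanova(dm, ["a"] * 3 + ["b"] * 3, n_permutations=99, seed=1)
        assert np.isfinite(res.F) or res.F == 0.0
        assert res.p == pytest.approx(1.0)

    def test_small_group_rejected(self):
        dm = DistanceMatrix(np.zeros((3, 3)), list("abc"))
        with pytest.raises(ValueError, match="2 samples"):
            permanova(dm, ["g1", "g1", "g2"], n_permutations=9)


class TestProcrustes:
    def _ordination(self, coords):
        coords = np.asarray(coords, float)
        return Ordination([f"s{i}" for i in range(len(coords))], coords,
                          np.ones(coords.shape[1]),
                          np.ones(coords.shape[1]) / coords.shape[1], "test")

    def test_identical_configurations_zero_residual(self, rng):
        coords = rng.normal(size=(10, 2))
        m2, p = procrustes_mc(self._ordination(coords),
                              self._ordination(coords),
                              n_permutations=99, seed=0)
        assert m2 == pytest.approx(0.0, abs=1e-12)
        assert p <= 0.05

    def test_rotation_invariance(self, rng):
        coords = rng.normal(size=(8, 2))
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        m2, _ = procrustes_mc(self._ordination(coords),
                              self._ordination(coords @ rot.T),
                              n_permutations=49, seed=0)
        assert m2 == pytest.approx(0.0, abs=1e-12)

    def test_independent_configurations_not_significant(self, rng):
        ps = []
        for _ in range(7):
            a = rng.normal(size=(20, 2))
            b = rng.normal(size=(20, 2))
            _, p = procrustes_mc(self._ordination(a), self._ordination(b),
                                 n_permutations=199, seed=3)
            ps.append(p)
        assert np.median(ps) > 0.1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            procrustes_mc(self._ordination([[0, 0], [1, 1]]),
                          self._ordination([[0, 0], [1, 1]]))
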