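"""Distance matrices, Mantel permutation test, PCO and the axis regression."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.ordination import pcoa as skbio_pcoa

from seismobiome import diststats


def random_dm(rng, n):
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(n)])


class TestEuclideanMatrix:
    def test_identical_rows_zero(self):
        df = pd.DataFrame([[1.0, 2.0]] * 3, index=list("abc"))
        assert np.allclose(diststats.euclidean_matrix(df).data, 0.0)

    def test_1d_inputs_are_absolute_differences(self):
        dm = diststats.euclidean_matrix([0.0, 3.0, 4.0])
        assert dm.data[0, 2] == 4.0 and dm.data[0, 1] == 3.0 and dm.data[1, 2] == 1.0

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(5, 10))
        dm = diststats.euclidean_matrix(mat)
        for i in range(5):
            for j in range(5):
                assert dm.data[i, j] == pytest.approx(
                    np.sqrt(((mat[i] - mat[j]) ** 2).sum()), abs=1e-12
                )

    def test_nan_rejected_with_location(self):
        df = pd.DataFrame({"x": [1.0, np.nan], "y": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="x"):
            diststats.euclidean_matrix(df)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        ab = pd.DataFrame({1: [10.0, 20.0], 2: [10.0, 20.0]}, index=["a", "b"])
        assert diststats.braycurtis_matrix(ab).data[0, 1] == 0.0
        ab2 = pd.DataFrame({1: [30.0, 0.0], 2: [0.0, 40.0]}, index=["a", "b"])
        assert diststats.braycurtis_matrix(ab2).data[0, 1] == 1.0

    def test_hand_formula(self):
        # samples (10,20,70) vs (20,20,60): sum|d| = 20, sum = 200 -> 0.1
        ab = pd.DataFrame({1: [10.0, 20.0, 70.0], 2: [20.0, 20.0, 60.0]}, index=list("abc"))
        assert diststats.braycurtis_matrix(ab).data[0, 1] == pytest.approx(0.1, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        ab = pd.DataFrame({1: [0.0, 0.0], 2: [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            diststats.braycurtis_matrix(ab)


class TestMantel:
    def test_identical_matrices_r_is_one(self):
        dm = random_dm(np.random.default_rng(0), 6)
        res = diststats.mantel(dm, dm, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_positive_affine_transform_r_is_one(self):
        dm = random_dm(np.random.default_rng(1), 6)
        dm2 = DistanceMatrix(2.5 * dm.data, ids=dm.ids)
        res = diststats.mantel(dm, dm2, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        a, b = random_dm(rng, 4), random_dm(rng, 4)
        res = diststats.mantel(a, b, tail="two-sided")
        assert res.method == "exact" and res.n_perm == 24
        # independent oracle: direct loop over all 4! relabelings with pearsonr
        iu = np.triu_indices(4, 1)
        r_obs = pearsonr(a.data[iu], b.data[iu])[0]
        hits = 0
        for perm in permutations(range(4)):
            bp = b.data[np.ix_(perm, perm)]
            if abs(pearsonr(a.data[iu], bp[iu])[0]) >= abs(r_obs) - 1e-12:
                hits += 1
        assert res.p == pytest.approx(hits / 24)
        assert res.r == pytest.approx(r_obs, abs=1e-12)

    def test_monte_carlo_approximates_exact_for_n4(self):
        rng = np.random.default_rng(11)
        a, b = random_dm(rng, 4), random_dm(rng, 4)
        exact = diststats.mantel(a, b)
        mc = diststats.mantel(a, b, n_perm=20000, seed=5, exhaustive_max_n=0)
        assert mc.method == "monte-carlo"
        assert mc.p == pytest.approx(exact.p, abs=0.02)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        a, b = random_dm(rng, 8), random_dm(rng, 8)
        r1 = diststats.mantel(a, b, n_perm=499, seed=42)
        r2 = diststats.mantel(a, b, n_perm=499, seed=42)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_r_agrees_with_skbio(self):
        rng = np.random.default_rng(9)
        a, b = random_dm(rng, 7), random_dm(rng, 7)
        ours = diststats.mantel(a, b, n_perm=999, seed=0)
        theirs_r, theirs_p, _ = skbio_mantel(a, b, permutations=999, alternative="two-sided")
        assert ours.r == pytest.approx(theirs_r, abs=1e-12)
        assert ours.p == pytest.approx(theirs_p, abs=0.05)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        a = random_dm(rng, 4)
        b = DistanceMatrix(a.data, ids=["w", "x", "y", "z"])
        with pytest.raises(ValueError, match="label"):
            diststats.mantel(a, b)

    def test_zero_variance_triangle_rejected(self):
        other = random_dm(np.random.default_rng(0), 4)
        flat = DistanceMatrix(1 - np.eye(4), ids=other.ids)
        with pytest.raises(ValueError, match="zero-variance"):
            diststats.mantel(flat, other)


class TestPco:
    def test_collinear_points_axis1_explains_all(self):
        dm = diststats.euclidean_matrix([0.0, 1.0, 3.0, 7.0])
        res = diststats.pco(dm)
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-8)
        assert res.n_positive == 1

    def test_equilateral_triangle_splits_50_50(self):
        dm = DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        res = diststats.pco(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-10)
        assert res.pct_variance[0] == pytest.approx(50.0, abs=1e-8)

    def test_euclidean_input_distances_reproduced(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 4))
        dm = diststats.euclidean_matrix(pts)
        res = diststats.pco(dm)
        recon = squareform(pdist(res.scores.to_numpy()))
        assert np.allclose(recon, dm.data, atol=1e-8)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(6)
        dm = random_dm(rng, 7)
        res = diststats.pco(dm)
        n = 7
        J = np.eye(n) - np.ones((n, n)) / n
        Bc = -0.5 * J @ (dm.data**2) @ J
        assert res.eigenvalues.sum() == pytest.approx(np.trace(Bc), rel=1e-10)

    def test_agrees_with_skbio_pcoa(self):
        rng = np.random.default_rng(8)
        dm = random_dm(rng, 6)
        ours = diststats.pco(dm)
        theirs = skbio_pcoa(dm, number_of_dimensions=5)
        np.testing.assert_allclose(
            ours.eigenvalues[: ours.n_positive], theirs.eigvals.values[: ours.n_positive],
            rtol=1e-8,
        )
        np.testing.assert_allclose(
            ours.pct_variance[0], 100 * theirs.proportion_explained.iloc[0], rtol=1e-8
        )

    def test_nonsymmetric_rejected(self):
        with pytest.raises(Exception):
            DistanceMatrix(np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]), ids=list("abc"))


class TestAxisRegression:
    def test_perfect_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        res = diststats.axis_regression(2 * x + 1, x)
        assert res.adj_r == pytest.approx(1.0)
        assert res.adj_p < 1e-6
        res_neg = diststats.axis_regression(-2 * x + 1, x)
        assert res_neg.adj_r == pytest.approx(-1.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=5)
        y = 1.5 * x + rng.normal(scale=0.5, size=5)
        res = diststats.axis_regression(y, x)
        # closed-form oracle
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        adj_r2 = 1 - (1 - r2) * 4 / 3
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        assert res.adj_r == pytest.approx(np.sign(slope) * np.sqrt(max(adj_r2, 0)), rel=1e-10)

    def test_orthogonal_covariate_r_near_zero(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        res = diststats.axis_regression(y, x)
        assert abs(res.adj_r) < 0.15

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            diststats.axis_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
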