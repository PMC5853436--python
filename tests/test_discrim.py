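import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

from rootlda.discrim import (
    CanonicalLDA,
    fit_lda,
    group_distance_map,
    mahalanobis_group_distance,
    mean_confidence_regions,
    pca,
    percentile_exemplars,
    scatter_matrices,
)
from rootlda.shape import classical_mds, distance_matrix
from rootlda.traits import build_trait_table, standardize


def rayleigh_argmax(H, E, n_random=200_000, seed=0):
    """Independent oracle: maximize a'Ha / a'Ea by random search + polish."""
    rng = np.random.default_rng(seed)
    p = H.shape[0]
    V = rng.normal(size=(n_random, p))
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    vals = np.einsum("ij,jk,ik->i", V, H, V) / np.einsum("ij,jk,ik->i", V, E, V)
    best = V[np.argmax(vals)]

    def neg(a):
        return -(a @ H @ a) / (a @ E @ a)

    res = minimize(neg, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return res.x / np.linalg.norm(res.x)


class TestScatterMatrices:
    def test_equal_means_give_zero_between(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        X2 = np.vstack([X, X])  # both groups share every point, so equal means
        labels = [0] * 10 + [1] * 10
        sc = scatter_matrices(X2, labels)
        assert np.allclose(sc.H, 0.0, atol=1e-10)

    def test_total_scatter_identity(self, grouped_data):
        X, labels = grouped_data
        sc = scatter_matrices(X, labels)
        Xc = X - X.mean(axis=0)
        assert np.allclose(sc.T, Xc.T @ Xc, atol=1e-8)
        assert np.allclose(sc.T, sc.H + sc.E, atol=1e-8 * np.linalg.norm(sc.T))

    def test_hand_computed_1d(self):
        """Groups {0,0} and {1,1}: H = 2*(0-.5)^2 + 2*(1-.5)^2 = 1, E = 0."""
        sc = scatter_matrices(np.array([0.0, 0.0, 1.0, 1.0]), [0, 0, 1, 1])
        assert sc.H[0, 0] == pytest.approx(1.0)
        assert sc.E[0, 0] == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="singleton"):
            scatter_matrices(np.zeros((3, 2)), [0, 1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            scatter_matrices(np.zeros((4, 2)), [0, 0, 0, 0])


class TestCanonicalLDA:
    def test_two_group_1d_matches_t_statistic(self):
        """g=2, p=1: the squared group-mean score gap equals
        t^2 * N / (n1 n2) for the pooled-variance two-sample t."""
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(0, 1, 12), rng.normal(1.0, 1, 18)
        X = np.concatenate([x1, x2])
        labels = [0] * 12 + [1] * 18
        m = fit_lda(X, labels)
        gap2 = (m.group_score_means_[1, 0] - m.group_score_means_[0, 0]) ** 2
        n1, n2 = 12, 18
        sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
        t = (x2.mean() - x1.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert gap2 == pytest.approx(t**2 * (1 / n1 + 1 / n2), rel=1e-10)

    def test_four_groups_give_three_discriminants(self, grouped_data):
        X, labels = grouped_data
        m = fit_lda(X, labels)
        assert m.scalings_.shape == (5, 3)
        assert m.eigenvalues_.shape == (3,)
        assert np.all(np.diff(m.eigenvalues_) <= 1e-12)

    def test_matches_rayleigh_oracle(self):
        rng = np.random.default_rng(7)
        for p, g in [(2, 2), (3, 3), (4, 4)]:
            n = 15 * g
            X = rng.normal(size=(n, p)) + np.repeat(rng.normal(size=(g, p)), 15, axis=0)
            labels = np.repeat(np.arange(g), 15)
            sc = scatter_matrices(X, labels)
            m = fit_lda(X, labels)
            a = rayleigh_argmax(sc.H, sc.E, seed=p)
            ld1 = m.scalings_[:, 0] / np.linalg.norm(m.scalings_[:, 0])
            assert abs(a @ ld1) > 0.999

    def test_within_class_score_covariance_is_identity(self, grouped_data):
        X, labels = grouped_data
        m = fit_lda(X, labels)
        sc = scatter_matrices(m.scores_, labels)
        Sw = sc.E / (len(labels) - len(sc.groups))
        assert np.allclose(Sw, np.eye(3), atol=1e-6)

    def test_eigenvalues_are_score_variance_ratios(self, grouped_data):
        X, labels = grouped_data
        m = fit_lda(X, labels)
        sc = scatter_matrices(m.scores_, labels)
        for j in range(3):
            assert sc.H[j, j] / sc.E[j, j] == pytest.approx(m.eigenvalues_[j], rel=1e-8)

    def test_fisher_direction_two_groups(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(size=(20, 4)), rng.normal(size=(20, 4)) + [1, 0.5, 0, 0]])
        labels = [0] * 20 + [1] * 20
        m = fit_lda(X, labels)
        sc = scatter_matrices(X, labels)
        Sw = sc.E / (40 - 2)
        fisher = np.linalg.solve(Sw, sc.group_means[0] - sc.group_means[1])
        c = (fisher @ m.scalings_[:, 0]) / (
            np.linalg.norm(fisher) * np.linalg.norm(m.scalings_[:, 0]))
        assert abs(c) > 1 - 1e-8

    def test_orientation_low_below_high(self, grouped_data):
        X, labels = grouped_data
        ref = np.where(np.isin(labels, [0, 1]), "low", "high")
        m = fit_lda(X, labels, orientation_ref=ref)
        assert m.scores_[ref == "low", 0].mean() < m.scores_[ref == "high", 0].mean()
        for j in range(1, 3):  # unreferenced discriminants: largest loading positive
            col = m.scalings_[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_transform_matches_training_scores(self, grouped_data):
        X, labels = grouped_data
        m = fit_lda(X, labels)
        assert np.allclose(m.transform(X), m.scores_)

    def test_singular_within_scatter_errors(self):
        X = np.zeros((8, 2))
        X[:, 0] = np.repeat([0.0, 1.0], 4)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_lda(X, [0] * 4 + [1] * 4)


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=40)
        X = np.outer(u, [1.0, 2.0, -1.0]) + 1e-8 * rng.normal(size=(40, 3))
        res = pca(X, 3)
        assert res.eigenvalues[0] == pytest.approx(3.0, abs=1e-5)
        assert np.all(res.eigenvalues[1:] < 1e-5)

    def test_scores_uncorrelated(self, grouped_data):
        X, _ = grouped_data
        res = pca(X, 4)
        C = np.cov(res.scores, rowvar=False)
        assert np.allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-10)

    def test_k_bounds(self, grouped_data):
        X, _ = grouped_data
        with pytest.raises(ValueError):
            pca(X, 6)


class TestMahalanobis:
    def test_identical_means_zero(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 3))
        assert mahalanobis_group_distance(A, A.copy()) == 0.0

    def test_1d_reduces_to_standardized_gap(self):
        A = np.array([[-1.0], [0.0], [1.0]])  # var 1
        B = A + 1.0
        assert mahalanobis_group_distance(A, B) == pytest.approx(1.0)

    def test_correlated_2d_matches_inverse_oracle(self):
        rng = np.random.default_rng(5)
        L = np.linalg.cholesky(np.array([[1.0, 0.9], [0.9, 1.0]]))
        A = rng.normal(size=(200, 2)) @ L.T
        B = rng.normal(size=(200, 2)) @ L.T + [1.0, 0.0]
        d = A.mean(axis=0) - B.mean(axis=0)
        S = ((len(A) - 1) * np.cov(A.T) + (len(B) - 1) * np.cov(B.T)) / (2 * len(A) - 2)
        want = np.sqrt(d @ np.linalg.inv(S) @ d)
        assert mahalanobis_group_distance(A, B) == pytest.approx(want, rel=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        A, B = rng.normal(size=(30, 3)), rng.normal(size=(25, 3)) + [1, -1, 0]
        d0 = mahalanobis_group_distance(A, B)
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            M = r2.normal(size=(3, 3)) + 3 * np.eye(3)
            b = r2.normal(size=3)
            assert mahalanobis_group_distance(A @ M.T + b, B @ M.T + b) == pytest.approx(
                d0, rel=1e-8)

    def test_singular_covariance_advises(self):
        A = np.zeros((3, 4))
        A[0, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError, match="pool"):
            mahalanobis_group_distance(A, A + [1, 2, 3, 4])


@pytest.fixture(scope="module")
def cohort_table(small_cohort):
    D = distance_matrix(small_cohort)
    emb = classical_mds(D, k=5)
    return standardize(build_trait_table(small_cohort, emb))


class TestGroupDistanceMap:
    def test_orderings_share_value_multiset(self, cohort_table):
        a = group_distance_map(cohort_table, ordering="line-pairs")
        b = group_distance_map(cohort_table, ordering="nitrate-blocks")
        assert sorted(a.labels) == sorted(b.labels)
        assert len(a.labels) == 17
        va = np.sort(a.values[np.triu_indices_from(a.values, 1)])
        vb = np.sort(b.values[np.triu_indices_from(b.values, 1)])
        assert np.allclose(va, vb, atol=1e-9)

    def test_line_pairs_ordering_adjacent(self, cohort_table):
        gmap = group_distance_map(cohort_table, ordering="line-pairs")
        lines = [lbl.split()[0] for lbl in gmap.labels]
        # every line's cells are contiguous
        for i in range(0, len(lines) - 1):
            if lines[i] == lines[i + 1]:
                assert gmap.labels[i].endswith("N-") and gmap.labels[i + 1].endswith("N+")

    def test_planted_outlier_line_is_lightest(self):
        """A line with wildly different architecture has the largest
        distances to every other cell."""
        import pandas as pd

        from rootlda.traits import TraitTable

        rng = np.random.default_rng(8)
        rows = []
        for li, line in enumerate(["A", "B", "C"]):
            for nitrate in ("low", "high"):
                for k in range(10):
                    base = rng.normal(size=3)
                    if line == "C":
                        base += 25.0
                    rows.append(dict(plant_id=f"{line}{nitrate}{k}", line=line,
                                     nupe_class="low" if line in ("A", "B") else "high",
                                     nitrate=nitrate,
                                     group_code=0 if line in ("A", "B") else 2,
                                     v1=base[0], v2=base[1], v3=base[2]))
        tab = TraitTable(data=pd.DataFrame(rows), variables=("v1", "v2", "v3"))
        gmap = group_distance_map(tab, ordering="line-pairs")
        labels = np.array([lbl.split()[0] for lbl in gmap.labels])
        mask_c = labels == "C"
        cross = gmap.values[np.ix_(mask_c, ~mask_c)]
        within_rest = gmap.values[np.ix_(~mask_c, ~mask_c)]
        assert cross.min() > within_rest.max()

    def test_small_cells_listed(self, cohort_table):
        with pytest.raises(ValueError, match="W145"):
            group_distance_map(cohort_table, min_cell_size=10)


class TestConfidenceRegions:
    def _model(self, n_per=100, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(size=(n_per, 3)) + s
                       for s in ([0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0])])
        labels = np.repeat(np.arange(4), n_per)
        return fit_lda(X, labels), labels

    def test_radius_matches_chi2_closed_form(self):
        """Unit within-covariance scores, n=100: radius ~ sqrt(chi2(0.99)/100)."""
        model, labels = self._model()
        ells = mean_confidence_regions(model, labels, level=0.99)
        want = np.sqrt(chi2.ppf(0.99, 2) / 100)
        for e in ells:
            assert np.all(np.abs(e.semi_axes - want) < 0.35 * want)

    def test_level_zero_degenerate(self):
        model, labels = self._model()
        for e in mean_confidence_regions(model, labels, level=0.0):
            assert np.allclose(e.semi_axes, 0.0)

    def test_area_scales_inversely_with_n(self):
        m1, l1 = self._model(n_per=100, seed=1)
        m2, l2 = self._model(n_per=200, seed=1)
        a1 = np.mean([e.area for e in mean_confidence_regions(m1, l1)])
        a2 = np.mean([e.area for e in mean_confidence_regions(m2, l2)])
        assert a1 / a2 == pytest.approx(2.0, rel=0.35)


class TestPercentileExemplars:
    def test_extremes_and_quantile_arithmetic(self):
        scores = np.arange(1.0, 11.0)
        ids = [f"p{i}" for i in range(1, 11)]
        out = percentile_exemplars(scores, ids, k=1)
        assert out[0][2] == ["p1"]  # percentile 0: the minimum
        assert out[-1][2] == ["p10"]
        q, qv, picks = out[5]
        assert (q, qv) == (0.5, 5.5)
        assert picks == ["p5"]  # |5-5.5| = |6-5.5|, tie broken by id

    def test_k_equal_n(self):
        scores = np.array([3.0, 1.0, 2.0])
        out = percentile_exemplars(scores, ["a", "b", "c"], k=3)
        for _, _, ids in out:
            assert sorted(ids) == ["a", "b", "c"]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            percentile_exemplars([np.nan, 1.0], ["a", "b"], k=1)
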