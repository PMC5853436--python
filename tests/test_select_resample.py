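import itertools

import numpy as np
import pytest

from rootlda.discrim import fit_lda, scatter_matrices
from rootlda.select_resample import (
    PERMUTATION_SCHEMES,
    Zeta2SubsetSelector,
    best_subsets,
    bootstrap_loadings,
    bootstrap_pvalue,
    permutation_test,
    zeta2,
)


def zeta2_oracle(X, labels, cols):
    """Independent re-derivation: U and r from raw group sums."""
    X = np.asarray(X, dtype=float)[:, list(cols)]
    labels = np.asarray(labels)
    groups = np.unique(labels)
    grand = X.mean(axis=0)
    H = np.zeros((X.shape[1],) * 2)
    E = np.zeros_like(H)
    for g in groups:
        sub = X[labels == g]
        d = sub.mean(axis=0) - grand
        H += len(sub) * np.outer(d, d)
        for row in sub:
            e = row - sub.mean(axis=0)
            E += np.outer(e, e)
    U = np.trace(np.linalg.inv(E) @ H)
    r = min(X.shape[1], len(groups) - 1)
    return U / (U + r)


class TestZeta2:
    def test_single_variable_two_groups_is_anova_r2(self):
        """q=1, g=2: zeta2 equals the squared correlation with the group
        indicator (the squared first canonical correlation)."""
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 25), rng.normal(1, 1, 25)])
        ind = np.repeat([0.0, 1.0], 25)
        s = zeta2(x, ind.astype(int))
        r2 = np.corrcoef(x, ind)[0, 1] ** 2
        assert s.zeta2 == pytest.approx(r2, rel=1e-10)
        assert s.r == 1

    def test_zero_between_scatter(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3))
        X2 = np.vstack([X, X])  # groups share every point: identical means
        labels = [0] * 6 + [1] * 6
        assert zeta2(X2, labels).zeta2 == pytest.approx(0.0, abs=1e-12)

    def test_limit_full_separation(self):
        rng = np.random.default_rng(1)
        X = np.repeat([[0.0], [10.0]], 10, axis=0) + 1e-6 * rng.normal(size=(20, 1))
        assert zeta2(X, [0] * 10 + [1] * 10).zeta2 > 0.999

    def test_bounds_and_r1_lambda_identity(self, grouped_data):
        X, labels = grouped_data
        for q in (1, 2, 5):
            s = zeta2(X, labels, subset=tuple(range(q)))
            assert 0.0 <= s.zeta2 <= 1.0
        # r = 1 route: two groups only
        two = np.isin(labels, [0, 2])
        s = zeta2(X[two], labels[two], subset=(0, 1, 2))
        lam = s.hotelling_lawley
        assert s.zeta2 == pytest.approx(lam / (1 + lam))

    def test_matches_oracle(self, grouped_data):
        X, labels = grouped_data
        for cols in [(0,), (1, 3), (0, 2, 4)]:
            assert zeta2(X, labels, subset=cols).zeta2 == pytest.approx(
                zeta2_oracle(X, labels, cols), rel=1e-10)


class TestBestSubsets:
    def test_matches_brute_force_enumeration(self, grouped_data):
        X, labels = grouped_data  # p=5
        got = best_subsets(X, labels)
        for q, score in zip(range(1, 5), got):
            best = max(
                (itertools.combinations(range(5), q)),
                key=lambda cols: (zeta2_oracle(X, labels, cols),
                                  tuple(-c for c in cols)),
            )
            names = tuple(f"x{i}" for i in best)
            assert score.subset == names
            assert score.zeta2 == pytest.approx(zeta2_oracle(X, labels, best), rel=1e-10)

    def test_planted_signal_variable_wins_size_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        labels = np.repeat([0, 1, 2], 20)
        X[:, 2] += labels * 3.0  # only column 2 separates the groups
        got = best_subsets(X, labels, sizes=[1])
        assert got[0].subset == ("x2",)

    def test_monotone_for_sizes_at_least_g_minus_1(self, grouped_data):
        X, labels = grouped_data  # g=4, so sizes >= 3 share r = 3
        got = {s.size: s.zeta2 for s in best_subsets(X, labels)}
        assert got[4] >= got[3] - 1e-12

    def test_incidence_matrix_shape(self, grouped_data):
        X, labels = grouped_data
        sel = Zeta2SubsetSelector(variable_names=list("abcde")).fit(X, labels)
        assert sel.incidence_.shape == (5, 4)
        assert sel.best_subsets_[-1].size == 4

    def test_size_out_of_range(self, grouped_data):
        X, labels = grouped_data
        with pytest.raises(ValueError):
            best_subsets(X, labels, sizes=[0])


class TestBootstrap:
    def test_printed_pvalue_formula(self):
        """A loading with mean -0.08 and SE 0.016 has two-sided normal
        p = 2 Phi(-5) = 5.7e-7."""
        p = bootstrap_pvalue(-0.08, 0.016)
        assert p == pytest.approx(5.733e-7, rel=1e-3)

    def test_seed_reproducibility_and_stability(self, grouped_data):
        X, labels = grouped_data
        a = bootstrap_loadings(X, labels, B=60, seed=9)
        b = bootstrap_loadings(X, labels, B=60, seed=9)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.sd, b.sd)
        c = bootstrap_loadings(X, labels, B=60, seed=10)
        assert np.all(np.abs(a.means - c.means) < 4 * np.maximum(a.sd, 1e-12))

    def test_sign_alignment_regression(self):
        """With well-separated groups, aligned bootstrap means stay close
        to the reference loadings; without alignment the mean collapses."""
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(size=(40, 3)) + s for s in ([0, 0, 0], [4, 0, 0])])
        labels = np.repeat([0, 1], 40)
        res = bootstrap_loadings(X, labels, B=100, seed=0)
        ref = res.reference[:, 0]
        mean = res.means[:, 0]
        cos = mean @ ref / (np.linalg.norm(mean) * np.linalg.norm(ref))
        assert abs(cos) > 0.9
        # deliberate misalignment: random flips wash the mean out
        flips = np.random.default_rng(0).choice([-1.0, 1.0], size=res.loadings.shape[0])
        washed = (res.loadings[:, :, 0] * flips[:, None]).mean(axis=0)
        assert np.linalg.norm(washed) < 0.5 * np.linalg.norm(mean)

    def test_se_is_sd_over_sqrt_B(self, grouped_data):
        X, labels = grouped_data
        res = bootstrap_loadings(X, labels, B=50, seed=1)
        assert np.allclose(res.se, res.sd / np.sqrt(50))
        assert res.correlation.shape == (15, 15)
        assert np.allclose(np.diag(res.correlation), 1.0)

    def test_needs_two_replicates(self, grouped_data):
        X, labels = grouped_data
        with pytest.raises(ValueError):
            bootstrap_loadings(X, labels, B=1)


class TestPermutation:
    def test_p_at_least_one_over_nplus1(self, grouped_data):
        X, labels = grouped_data
        res = permutation_test(X, labels, scheme="0123", n_perm=99, seed=0)
        assert res.p_value >= 1.0 / 100.0
        assert np.all((res.null_statistics >= 0) & (res.null_statistics <= 1))

    def test_matches_exact_enumeration(self):
        """6 plants, 2 groups: Monte-Carlo p within binomial error of the
        exact p over all 20 distinct label assignments."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2))
        X[3:, 0] += 2.0
        labels = np.array([0, 0, 0, 1, 1, 1])
        obs = zeta2(X, labels).zeta2
        exact_null = [
            zeta2(X, np.array(perm)).zeta2
            for perm in sorted(set(itertools.permutations(labels)))
        ]
        p_exact = np.mean([z >= obs for z in exact_null])
        n_perm = 4000
        res = permutation_test(X, labels, scheme="01", n_perm=n_perm, seed=1)
        tol = 2 * np.sqrt(p_exact * (1 - p_exact) / n_perm) + 1 / n_perm
        assert abs(res.p_value - p_exact) <= tol

    def test_schemes_leave_held_out_groups_fixed(self, grouped_data):
        """Permuting (0,1) must not move mass between groups 2 and 3: its
        null should differ from the all-groups null."""
        X, labels = grouped_data
        r01 = permutation_test(X, labels, scheme="01", n_perm=150, seed=2)
        rall = permutation_test(X, labels, scheme="0123", n_perm=150, seed=2)
        assert r01.observed == pytest.approx(rall.observed)
        assert r01.null_statistics.mean() > rall.null_statistics.mean()

    def test_invariant_to_within_group_relabeling(self, grouped_data):
        X, labels = grouped_data
        res1 = permutation_test(X, labels, scheme="01v23", n_perm=200, seed=3)
        # swap two plants inside group 0: the statistic and null are unchanged
        idx = np.arange(len(labels))
        i, j = np.flatnonzero(labels == 0)[:2]
        idx[[i, j]] = idx[[j, i]]
        res2 = permutation_test(X[idx], labels[idx], scheme="01v23", n_perm=200, seed=3)
        assert res1.observed == pytest.approx(res2.observed)
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_unknown_scheme_and_bad_block(self, grouped_data):
        X, labels = grouped_data
        with pytest.raises(ValueError, match="scheme"):
            permutation_test(X, labels, scheme="nope")
        only01 = np.isin(labels, [0, 1])
        with pytest.raises(ValueError, match="block"):
            permutation_test(X[only01], labels[only01], scheme="23", n_perm=10)

    def test_all_six_schemes_run(self, grouped_data):
        X, labels = grouped_data
        for scheme in PERMUTATION_SCHEMES:
            res = permutation_test(X, labels, scheme=scheme, n_perm=50, seed=4)
            assert 0 < res.p_value <= 1
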