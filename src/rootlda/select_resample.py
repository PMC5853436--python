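"""Variable-subset selection (zeta-squared), loading bootstrap, permutations.

The subset-selection criterion is the normalized Hotelling-Lawley trace:
for a variable subset S, U = tr(E_S^-1 H_S) and zeta^2 = U / (U + r) with
r = min(|S|, g - 1).  It lies in [0, 1], equals the squared first
canonical correlation whenever r = 1, and is monotone in U, so the best
zeta^2 over subsets of a given size is found by exhaustive enumeration.

Bootstrap inference resamples plants with replacement, refits the
discriminant on the chosen subset, aligns each replicate discriminant's
sign with the reference fit (discriminants are only defined up to sign),
and summarizes loading distributions.  Block-permutation tests shuffle
group labels within stated blocks of groups and recompute zeta^2 against
the full grouping, giving restricted nulls such as "nitrate within the
low-NUpE plants".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .discrim import CanonicalLDA, scatter_matrices

__all__ = [
    "SubsetScore",
    "zeta2",
    "best_subsets",
    "Zeta2SubsetSelector",
    "BootstrapResult",
    "bootstrap_loadings",
    "LoadingBootstrap",
    "PERMUTATION_SCHEMES",
    "PermutationResult",
    "permutation_test",
    "BlockPermutationTest",
]


@dataclass(frozen=True)
class SubsetScore:
    """zeta^2 score of one variable subset."""

    subset: tuple[str, ...]
    size: int
    zeta2: float
    hotelling_lawley: float  # U = tr(E_S^-1 H_S)
    r: int


def _zeta2_from_scatter(H: np.ndarray, E: np.ndarray, g: int, q: int) -> tuple[float, float, int]:
    r = min(q, g - 1)
    U = float(np.trace(np.linalg.solve(E, H)))
    U = max(U, 0.0)
    return U / (U + r), U, r


def zeta2(X, labels, subset: tuple[int, ...] | None = None,
          variable_names: list[str] | None = None) -> SubsetScore:
    """zeta^2 = U / (U + r) for the given column subset (default: all)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cols = tuple(range(X.shape[1])) if subset is None else tuple(subset)
    sc = scatter_matrices(X[:, cols], labels)
    g = len(sc.groups)
    try:
        z, U, r = _zeta2_from_scatter(sc.H, sc.E, g, len(cols))
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"within-scatter singular for subset {cols}; zeta2 undefined"
        ) from None
    names = (tuple(variable_names[i] for i in cols) if variable_names is not None
             else tuple(f"x{i}" for i in cols))
    return SubsetScore(subset=names, size=len(cols), zeta2=z, hotelling_lawley=U, r=r)


class Zeta2SubsetSelector(BaseEstimator):
    """Exhaustive best-subset search under the zeta^2 criterion.

    For every size in ``sizes`` (default 1..p-1) the subset maximizing
    zeta^2 is found by full enumeration (ties broken by lexicographic
    column order; subsets with singular within-scatter are skipped and
    counted).  For p > ``max_exhaustive_p`` a greedy forward search is
    used instead, with a warning.

    Attributes (after fit): ``best_subsets_`` (one SubsetScore per size),
    ``incidence_`` (variables x sizes membership matrix),
    ``skipped_singular_``.
    """

    def __init__(self, sizes=None, max_exhaustive_p: int = 20,
                 variable_names: list[str] | None = None):
        self.sizes = sizes
        self.max_exhaustive_p = max_exhaustive_p
        self.variable_names = variable_names

    def fit(self, X, y) -> "Zeta2SubsetSelector":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        labels = np.asarray(y)
        sizes = list(self.sizes) if self.sizes is not None else list(range(1, p))
        if any(s < 1 or s > p for s in sizes):
            raise ValueError(f"subset sizes must be in 1..{p}")
        names = (list(self.variable_names) if self.variable_names is not None
                 else [f"x{i}" for i in range(p)])

        # one pass over the full scatter; subsets reuse its slices
        sc = scatter_matrices(X, labels)
        g = len(sc.groups)
        skipped = 0
        results: list[SubsetScore] = []

        def score(cols: tuple[int, ...]) -> float | None:
            nonlocal skipped
            idx = np.array(cols)
            Hs = sc.H[np.ix_(idx, idx)]
            Es = sc.E[np.ix_(idx, idx)]
            try:
                z, _, _ = _zeta2_from_scatter(Hs, Es, g, len(cols))
            except np.linalg.LinAlgError:
                skipped += 1
                return None
            return z

        if p <= self.max_exhaustive_p:
            for q in sizes:
                best: tuple[float, tuple[int, ...]] | None = None
                for cols in itertools.combinations(range(p), q):
                    z = score(cols)
                    if z is None:
                        continue
                    if best is None or z > best[0] + 1e-15:
                        best = (z, cols)
                if best is None:
                    raise np.linalg.LinAlgError(f"every subset of size {q} was singular")
                idx = np.array(best[1])
                z, U, r = _zeta2_from_scatter(sc.H[np.ix_(idx, idx)],
                                              sc.E[np.ix_(idx, idx)], g, q)
                results.append(SubsetScore(subset=tuple(names[i] for i in best[1]),
                                           size=q, zeta2=z, hotelling_lawley=U, r=r))
        else:
            import warnings

            warnings.warn(
                f"p={p} > {self.max_exhaustive_p}: falling back to greedy forward search",
                stacklevel=2,
            )
            chosen: list[int] = []
            remaining = list(range(p))
            for q in range(1, max(sizes) + 1):
                best = None
                for c in remaining:
                    z = score(tuple(sorted(chosen + [c])))
                    if z is not None and (best is None or z > best[0] + 1e-15):
                        best = (z, c)
                if best is None:
                    raise np.linalg.LinAlgError(f"greedy step {q}: all candidates singular")
                chosen.append(best[1])
                remaining.remove(best[1])
                if q in sizes:
                    cols = tuple(sorted(chosen))
                    idx = np.array(cols)
                    z, U, r = _zeta2_from_scatter(sc.H[np.ix_(idx, idx)],
                                                  sc.E[np.ix_(idx, idx)], g, q)
                    results.append(SubsetScore(subset=tuple(names[i] for i in cols),
                                               size=q, zeta2=z, hotelling_lawley=U, r=r))

        self.best_subsets_ = sorted(results, key=lambda s: s.size)
        self.skipped_singular_ = skipped
        self.variable_names_ = names
        self.incidence_ = np.array(
            [[v in s.subset for s in self.best_subsets_] for v in names]
        )
        return self


def best_subsets(X, labels, sizes=None, variable_names=None) -> list[SubsetScore]:
    """Functional wrapper around :class:`Zeta2SubsetSelector`."""
    sel = Zeta2SubsetSelector(sizes=sizes, variable_names=variable_names).fit(X, labels)
    return sel.best_subsets_


@dataclass
class BootstrapResult:
    """Bootstrap distribution of the discriminant loadings."""

    n_replicates: int
    variable_names: list[str]
    loadings: np.ndarray  # (B, p, r), sign-aligned to the reference fit
    reference: np.ndarray  # (p, r)
    means: np.ndarray  # (p, r)
    sd: np.ndarray  # (p, r) bootstrap standard deviation
    se: np.ndarray  # (p, r) sd / sqrt(B): the Table-style standard error
    p_values: np.ndarray  # (p, r): 2 Phi(-|mean| / se)
    correlation: np.ndarray  # (p*r, p*r) correlation of stacked loadings
    covariance: np.ndarray
    redrawn: int  # replicates redrawn because a group vanished
    seed: int

    def table(self):
        """Mean (SE) per variable and discriminant, Table-style."""
        import pandas as pd

        r = self.means.shape[1]
        return pd.DataFrame(
            {f"LD{j + 1}": [f"{self.means[i, j]:.2f} ({self.se[i, j]:.3f})"
                            for i in range(len(self.variable_names))]
             for j in range(r)},
            index=self.variable_names,
        )


def bootstrap_pvalue(mean: float, se: float) -> float:
    """Two-sided normal p-value for a loading: 2 Phi(-|mean| / SE)."""
    if se == 0:
        return 0.0 if mean != 0 else 1.0
    return float(2.0 * norm.cdf(-abs(mean) / se))


class LoadingBootstrap(BaseEstimator):
    """Case-resampling bootstrap of discriminant loadings.

    Each replicate resamples the N plants with replacement, refits the
    discriminant analysis on the chosen variable subset, orders
    discriminants by eigenvalue and flips any discriminant whose loading
    vector has negative dot product with the reference fit.  Replicates in
    which a group disappears entirely are redrawn (and counted).
    """

    def __init__(self, n_replicates: int = 1000, seed: int = 0,
                 variable_names: list[str] | None = None):
        self.n_replicates = n_replicates
        self.seed = seed
        self.variable_names = variable_names

    def fit(self, X, y) -> "LoadingBootstrap":
        if self.n_replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        X = np.asarray(X, dtype=float)
        labels = np.asarray(y)
        n = X.shape[0]
        names = (list(self.variable_names) if self.variable_names is not None
                 else [f"x{i}" for i in range(X.shape[1])])
        ref = CanonicalLDA(variable_names=names).fit(X, labels)
        A_ref = ref.scalings_
        groups = set(ref.classes_.tolist())
        rng = np.random.default_rng(self.seed)
        B = self.n_replicates
        out = np.empty((B, *A_ref.shape))
        redrawn = 0
        b = 0
        while b < B:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if set(np.unique(lab).tolist()) != groups or np.min(np.bincount(
                    np.unique(lab, return_inverse=True)[1])) < 2:
                redrawn += 1
                continue
            try:
                rep = CanonicalLDA().fit(X[idx], lab)
            except np.linalg.LinAlgError:
                redrawn += 1
                continue
            A = rep.scalings_
            flip = np.sign(np.sum(A * A_ref, axis=0))
            flip[flip == 0] = 1.0
            out[b] = A * flip
            b += 1

        means = out.mean(axis=0)
        sd = out.std(axis=0, ddof=1)
        se = sd / np.sqrt(B)
        pv = np.vectorize(bootstrap_pvalue)(means, se)
        flat = out.reshape(B, -1)
        cov = np.cov(flat, rowvar=False)
        d = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
        corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        self.result_ = BootstrapResult(
            n_replicates=B, variable_names=names, loadings=out, reference=A_ref,
            means=means, sd=sd, se=se, p_values=pv, correlation=corr,
            covariance=cov, redrawn=redrawn, seed=self.seed,
        )
        self.reference_model_ = ref
        return self


def bootstrap_loadings(X, labels, B: int = 1000, seed: int = 0,
                       variable_names=None) -> BootstrapResult:
    """Functional wrapper around :class:`LoadingBootstrap`."""
    return LoadingBootstrap(n_replicates=B, seed=seed,
                            variable_names=variable_names).fit(X, labels).result_


# The six permutation schemes: each is a list of blocks of group codes;
# labels are shuffled uniformly within each block, groups outside every
# block keep their labels fixed.
PERMUTATION_SCHEMES: dict[str, list[tuple[int, ...]]] = {
    "0123": [(0, 1, 2, 3)],
    "01v23": [(0, 1), (2, 3)],
    "02v13": [(0, 2), (1, 3)],
    "03v12": [(0, 3), (1, 2)],
    "01": [(0, 1)],
    "23": [(2, 3)],
}


@dataclass
class PermutationResult:
    """One block-permutation test of the zeta^2 statistic."""

    scheme: str
    observed: float
    null_statistics: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    statistic_subset: tuple[str, ...] | None = None


class BlockPermutationTest(BaseEstimator):
    """Permutation significance test for the multi-group zeta^2 statistic.

    The statistic is zeta^2 of the (fixed) variable subset against the
    full four-group labelling.  Under each permutation the labels are
    shuffled within the scheme's blocks only, preserving group sizes, and
    the statistic is recomputed.  The p-value uses the add-one estimator
    p = (1 + #{null >= observed}) / (1 + n_permutations), so it is never 0
    and the observed value always ranks within its own null.
    """

    def __init__(self, scheme: str = "0123", n_permutations: int = 10000,
                 seed: int = 0, subset: tuple[int, ...] | None = None,
                 variable_names: list[str] | None = None):
        self.scheme = scheme
        self.n_permutations = n_permutations
        self.seed = seed
        self.subset = subset
        self.variable_names = variable_names

    def fit(self, X, y) -> "BlockPermutationTest":
        if self.scheme not in PERMUTATION_SCHEMES:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; choose from {sorted(PERMUTATION_SCHEMES)}"
            )
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = np.asarray(y)
        cols = tuple(self.subset) if self.subset is not None else tuple(range(X.shape[1]))
        Xs = X[:, cols]
        blocks = PERMUTATION_SCHEMES[self.scheme]
        present = set(np.unique(labels).tolist())
        for block in blocks:
            in_block = [g for g in block if g in present]
            if len(in_block) < 2:
                raise ValueError(
                    f"scheme {self.scheme!r}: block {block} has fewer than 2 "
                    f"groups present in the data"
                )
        obs = zeta2(Xs, labels).zeta2
        rng = np.random.default_rng(self.seed)
        block_members = [np.flatnonzero(np.isin(labels, block)) for block in blocks]
        null = np.empty(self.n_permutations)
        perm = labels.copy()
        for t in range(self.n_permutations):
            perm[:] = labels
            for members in block_members:
                perm[members] = perm[members[rng.permutation(len(members))]]
            null[t] = zeta2(Xs, perm).zeta2
        p = (1.0 + np.sum(null >= obs)) / (1.0 + self.n_permutations)
        names = (tuple(self.variable_names[i] for i in cols)
                 if self.variable_names is not None else None)
        self.result_ = PermutationResult(
            scheme=self.scheme, observed=obs, null_statistics=null, p_value=float(p),
            n_permutations=self.n_permutations, seed=self.seed, statistic_subset=names,
        )
        return self

    @property
    def p_value_(self) -> float:
        return self.result_.p_value


def permutation_test(X, labels, scheme: str = "0123", n_perm: int = 10000,
                     seed: int = 0, subset=None, variable_names=None) -> PermutationResult:
    """Functional wrapper around :class:`BlockPermutationTest`."""
    return BlockPermutationTest(
        scheme=scheme, n_permutations=n_perm, seed=seed, subset=subset,
        variable_names=variable_names,
    ).fit(X, labels).result_
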