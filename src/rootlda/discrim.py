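"""Multi-group linear discriminant analysis and Mahalanobis group distances.

The discriminant solves the generalized eigenproblem of E^-1 H, where H
and E are the between- and within-group scatter matrices, via whitening
with the Cholesky factor of E.  Loadings a are scaled so that
a' S_w a = 1 with S_w = E / (N - g) the pooled within-class covariance —
the convention under which scores have unit pooled within-class variance
and loading magnitudes are comparable across discriminants.  Each
discriminant's sign is fixed either by a reference contrast (the group
coded "low" gets the lower mean score) or, failing that, so the loading
of largest magnitude is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin

from .traits import TraitTable

__all__ = [
    "ScatterDecomposition",
    "scatter_matrices",
    "CanonicalLDA",
    "fit_lda",
    "PCAResult",
    "pca",
    "mahalanobis_group_distance",
    "GroupDistanceMap",
    "group_distance_map",
    "ConfidenceEllipse",
    "mean_confidence_regions",
    "percentile_exemplars",
]


@dataclass
class ScatterDecomposition:
    """Between (H), within (E) and total (T = H + E) scatter matrices."""

    H: np.ndarray
    E: np.ndarray
    T: np.ndarray
    groups: list
    group_sizes: np.ndarray
    grand_mean: np.ndarray
    group_means: np.ndarray  # (g, p)


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    return X


def scatter_matrices(X, labels) -> ScatterDecomposition:
    """Between-, within- and total-scatter decomposition of grouped data.

    H = sum_g n_g (m_g - m)(m_g - m)', E = sum_g sum_{i in g}
    (x_i - m_g)(x_i - m_g)', T = H + E.
    """
    X = _as_matrix(X)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match rows of X")
    groups, inv = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inv)
    if np.any(sizes < 2):
        bad = [groups[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"singleton groups not allowed: {bad}")
    n, p = X.shape
    if n <= p:
        warnings.warn(f"N={n} <= p={p}: scatter matrices may be singular", stacklevel=2)
    grand = X.mean(axis=0)
    means = np.vstack([X[inv == g].mean(axis=0) for g in range(len(groups))])
    dm = means - grand
    H = (dm * sizes[:, None]).T @ dm
    resid = X - means[inv]
    E = resid.T @ resid
    return ScatterDecomposition(H=H, E=E, T=H + E, groups=list(groups),
                                group_sizes=sizes, grand_mean=grand, group_means=means)


def _orient(loadings: np.ndarray, scores: np.ndarray, labels_ref, grand_mean) -> np.ndarray:
    """Return +-1 sign per discriminant (see module docstring)."""
    r = loadings.shape[1]
    signs = np.ones(r)
    start = 0
    if labels_ref is not None:
        ref = np.asarray(labels_ref)
        levels = np.unique(ref)
        if len(levels) != 2:
            raise ValueError("orientation_ref must be binary")
        lo, hi = levels[0], levels[1]  # sorted: 'high' < 'low', 0 < 1
        if {str(lo), str(hi)} == {"low", "high"}:
            lo, hi = "low", "high"
        if scores[ref == lo, 0].mean() > scores[ref == hi, 0].mean():
            signs[0] = -1.0
        start = 1
    for j in range(start, r):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            signs[j] = -1.0
    return signs


class CanonicalLDA(BaseEstimator, TransformerMixin):
    """Multi-group canonical linear discriminant analysis.

    Fits r = min(p, g - 1) discriminants ordered by decreasing eigenvalue
    of E^-1 H, with unit pooled within-class score variance (see module
    docstring).  ``transform`` maps new data to score space relative to
    the training grand mean.

    Attributes (after fit)
    ----------------------
    scalings_ : (p, r) loadings matrix (columns LD1..LDr)
    eigenvalues_ : (r,) between/within variance ratio per discriminant
    scores_ : (N, r) training scores
    group_score_means_ : (g, r) group means in score space
    scatter_ : ScatterDecomposition
    classes_ : group labels in sorted order
    """

    def __init__(self, variable_names: list[str] | None = None):
        self.variable_names = variable_names

    def fit(self, X, y, orientation_ref=None) -> "CanonicalLDA":
        X = _as_matrix(X)
        sc = scatter_matrices(X, y)
        n, p = X.shape
        g = len(sc.groups)
        r = min(p, g - 1)
        if r == 0:
            raise ValueError("no discriminants: need at least 2 groups")
        try:
            L = np.linalg.cholesky(sc.E)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "within-group scatter E is singular; consider subset selection "
                "or more plants per group"
            ) from None
        Li = np.linalg.inv(L)
        M = Li @ sc.H @ Li.T
        w, V = np.linalg.eigh((M + M.T) / 2.0)
        order = np.argsort(w)[::-1][:r]
        w = np.maximum(w[order], 0.0)
        A = Li.T @ V[:, order]  # a' E a = 1
        A = A * np.sqrt(n - g)  # a' S_w a = 1,  S_w = E / (N - g)
        scores = (X - sc.grand_mean) @ A
        if orientation_ref is not None:
            ref = np.asarray(orientation_ref)
            if ref.shape[0] != n:
                raise ValueError("orientation_ref length must match rows of X")
        else:
            ref = None
        signs = _orient(A, scores, ref, sc.grand_mean)
        A = A * signs
        scores = scores * signs

        labels = np.asarray(y)
        self.scalings_ = A
        self.eigenvalues_ = w
        self.scores_ = scores
        self.grand_mean_ = sc.grand_mean
        self.scatter_ = sc
        self.classes_ = np.array(sc.groups)
        self.group_score_means_ = np.vstack(
            [scores[labels == gl].mean(axis=0) for gl in sc.groups]
        )
        self.n_features_in_ = p
        self.variable_names_ = (
            list(self.variable_names) if self.variable_names is not None
            else [f"x{i}" for i in range(p)]
        )
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return (X - self.grand_mean_) @ self.scalings_

    @property
    def loadings_(self) -> np.ndarray:
        return self.scalings_

    def loadings_frame(self) -> pd.DataFrame:
        r = self.scalings_.shape[1]
        return pd.DataFrame(self.scalings_, index=self.variable_names_,
                            columns=[f"LD{i + 1}" for i in range(r)])

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues_.tolist(),
            "variables": self.variable_names_,
            "loadings": {c: self.loadings_frame()[c].round(12).to_dict()
                         for c in self.loadings_frame().columns},
            "groups": [str(g) for g in self.classes_],
            "group_score_means": self.group_score_means_.tolist(),
        }


def fit_lda(X, labels, orientation_ref=None, variable_names=None) -> CanonicalLDA:
    """Functional wrapper: fit a :class:`CanonicalLDA` and return it."""
    return CanonicalLDA(variable_names=variable_names).fit(
        X, labels, orientation_ref=orientation_ref
    )


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (p, k) eigenvectors of the correlation matrix
    eigenvalues: np.ndarray


def pca(X, k: int) -> PCAResult:
    """PCA on the correlation matrix with a deterministic sign rule."""
    X = _as_matrix(X)
    p = X.shape[1]
    if k > p:
        raise ValueError(f"k={k} exceeds number of variables p={p}")
    C = np.corrcoef(X, rowvar=False)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:k]
    w, V = w[order], V[:, order]
    for j in range(k):  # largest-|entry| positive, as for the MDS axes
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return PCAResult(scores=Xc @ V, loadings=V, eigenvalues=w)


def mahalanobis_group_distance(A, B, pooled_cov: np.ndarray | None = None) -> float:
    """Mahalanobis distance between the means of two samples.

    D_M = sqrt((m_A - m_B)' S^-1 (m_A - m_B)).  By default S is the
    pair-pooled within-group covariance of A and B; pass ``pooled_cov``
    to use a covariance pooled over all groups instead (more stable when
    p is large relative to the pair's size).
    """
    A, B = _as_matrix(A), _as_matrix(B)
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must have the same number of variables")
    d = A.mean(axis=0) - B.mean(axis=0)
    if not np.any(d):  # identical means: zero regardless of covariance
        return 0.0
    if pooled_cov is None:
        na, nb = A.shape[0], B.shape[0]
        if na + nb - 2 < A.shape[1]:
            raise np.linalg.LinAlgError(
                "pair-pooled covariance is singular (too few plants for p "
                "variables); use all-groups pooling or fewer variables"
            )
        S = ((na - 1) * np.atleast_2d(np.cov(A, rowvar=False))
             + (nb - 1) * np.atleast_2d(np.cov(B, rowvar=False))) / (na + nb - 2)
    else:
        S = np.atleast_2d(np.asarray(pooled_cov, dtype=float))
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; use all-groups pooling or shrinkage"
        ) from None
    return float(np.sqrt(max(d @ sol, 0.0)))


@dataclass
class GroupDistanceMap:
    """Mahalanobis distances between line x nitrate cells, ordered for display."""

    labels: list[str]  # e.g. "W145 N-"
    values: np.ndarray
    ordering: str  # "line-pairs" | "nitrate-blocks"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _cell_key(line: str, nitrate: str) -> str:
    return f"{line} {'N+' if nitrate == 'high' else 'N-'}"


def group_distance_map(
    table: TraitTable,
    ordering: str = "line-pairs",
    pooling: str = "all-groups",
    min_cell_size: int = 2,
) -> GroupDistanceMap:
    """Pairwise Mahalanobis distances among all line x nitrate cells.

    ``ordering`` controls the display order of the heat map: "line-pairs"
    puts each line's low- and high-nitrate cells next to each other (low-
    then high-NUpE lines); "nitrate-blocks" groups cells by nitrate level
    within each NUpE block.  ``pooling`` is "all-groups" (within-cell
    covariance pooled over every cell, the default) or "pair".
    """
    if ordering not in ("line-pairs", "nitrate-blocks"):
        raise ValueError(f"unknown ordering {ordering!r}")
    if pooling not in ("all-groups", "pair"):
        raise ValueError(f"unknown pooling {pooling!r}")
    df = table.data
    X = table.values
    cells: dict[tuple[str, str], np.ndarray] = {}
    meta: dict[tuple[str, str], str] = {}
    for (line, nitrate), idx in df.groupby(["line", "nitrate"], sort=False).groups.items():
        rows = df.index.get_indexer(idx)
        cells[(line, nitrate)] = X[rows]
        meta[(line, nitrate)] = df.loc[idx[0], "nupe_class"]
    small = [k for k, v in cells.items() if v.shape[0] < min_cell_size]
    if small:
        raise ValueError(f"cells below minimum size {min_cell_size}: "
                         + ", ".join(_cell_key(*k) for k in small))

    lines_in_order: list[str] = []
    for line in df["line"]:
        if line not in lines_in_order:
            lines_in_order.append(line)
    low_lines = [l for l in lines_in_order if meta.get((l, "low"), meta.get((l, "high"))) == "low"]
    high_lines = [l for l in lines_in_order if l not in low_lines]

    def present(line, nitrate):
        return (line, nitrate) in cells

    keys: list[tuple[str, str]] = []
    if ordering == "line-pairs":
        for line in low_lines + high_lines:
            for nitrate in ("low", "high"):
                if present(line, nitrate):
                    keys.append((line, nitrate))
    else:
        for block in (low_lines, high_lines):
            for nitrate in ("low", "high"):
                for line in block:
                    if present(line, nitrate):
                        keys.append((line, nitrate))

    pooled = None
    if pooling == "all-groups":
        p = X.shape[1]
        E = np.zeros((p, p))
        dof = 0
        for v in cells.values():
            resid = v - v.mean(axis=0)
            E += resid.T @ resid
            dof += v.shape[0] - 1
        pooled = E / dof

    n = len(keys)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = mahalanobis_group_distance(
                cells[keys[i]], cells[keys[j]], pooled_cov=pooled
            )
    return GroupDistanceMap(labels=[_cell_key(*k) for k in keys], values=D,
                            ordering=ordering)


@dataclass
class ConfidenceEllipse:
    """A normal-theory confidence region for one group's mean score."""

    group: object
    center: np.ndarray  # (2,)
    semi_axes: np.ndarray  # (2,) descending
    angle_deg: float  # orientation of the major axis
    level: float

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


def mean_confidence_regions(
    model: CanonicalLDA, labels, level: float = 0.99, dims: tuple[int, int] = (0, 1)
) -> list[ConfidenceEllipse]:
    """Per-group confidence ellipses for mean scores in two discriminants.

    The region is {mu + u : u' (Sigma_g / n_g)^-1 u <= chi2_2(level)} with
    Sigma_g the group's empirical 2x2 score covariance.
    """
    if not (0.0 <= level < 1.0):
        raise ValueError("level must be in [0, 1)")
    labels = np.asarray(labels)
    S = model.scores_[:, list(dims)]
    q = chi2.ppf(level, df=2) if level > 0 else 0.0
    out = []
    for gl in model.classes_:
        pts = S[labels == gl]
        n_g = pts.shape[0]
        if n_g < 3:
            raise ValueError(f"group {gl!r} has fewer than 3 members")
        cov = np.cov(pts, rowvar=False) / n_g
        w, V = np.linalg.eigh(cov)
        if w[0] <= 0:
            raise ValueError(f"group {gl!r} has a degenerate score covariance")
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        out.append(ConfidenceEllipse(
            group=gl, center=pts.mean(axis=0), semi_axes=np.sqrt(q * w),
            angle_deg=float(np.degrees(np.arctan2(V[1, 0], V[0, 0]))), level=level,
        ))
    return out


def percentile_exemplars(
    scores, plant_ids, k: int = 5, step: float = 0.1
) -> list[tuple[float, float, list[str]]]:
    """Plants nearest each LD1-score percentile.

    For each percentile q in {0, step, 2 step, ..., 1} of the score vector
    (linear-interpolation quantile), returns (q, percentile value, the k
    plant ids minimizing |score - value|, ties broken by plant id).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    plant_ids = list(plant_ids)
    if len(plant_ids) != len(scores):
        raise ValueError("plant_ids length must match scores")
    if k > len(scores):
        raise ValueError("k exceeds the number of plants")
    qs = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    out = []
    for q in qs:
        qv = float(np.quantile(scores, q))
        ranked = sorted(zip(np.abs(scores - qv), plant_ids))
        out.append((float(q), qv, [pid for _, pid in ranked[:k]]))
    return out
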