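"""Pairwise distance between root systems and classical MDS shape coordinates.

The distance treats each root system as two sets of curves (seminal and
lateral), re-anchored at the seed and resampled to ``m`` points equally
spaced in arc length.  The cost between two curves is the root mean square
of the pointwise Euclidean gaps; curve sets are matched by a minimum-cost
assignment, and any unmatched curve pays its RMS distance to the
degenerate curve at the origin, so differing root counts contribute.  The
total is the seminal cost plus ``lateral_weight`` times the lateral cost.
No normalization by root count is applied: size information is retained
deliberately, so the resulting shape coordinates can track plant size.

The construction is symmetric and zero on identical systems, but the
assignment-plus-penalty structure does not guarantee the triangle
inequality; classical (Torgerson) MDS tolerates this by discarding
negative eigenvalue mass, which is recorded in the embedding result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from .rootgen import RootCurve, RootSystem

__all__ = [
    "DistanceParams",
    "DistanceMatrix",
    "EmbeddingResult",
    "resample_curve",
    "system_distance",
    "distance_matrix",
    "ClassicalMDS",
    "classical_mds",
]


@dataclass(frozen=True)
class DistanceParams:
    """Knobs of the root-system distance: resample count and lateral weight."""

    m: int = 50
    lateral_weight: float = 1.0

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("resample count m must be >= 2")
        if self.lateral_weight < 0:
            raise ValueError("lateral_weight must be >= 0")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between the plants of a cohort."""

    plant_ids: list[str]
    values: np.ndarray
    params: DistanceParams = field(default_factory=DistanceParams)

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        n = len(self.plant_ids)
        if D.shape != (n, n):
            raise ValueError(f"distance matrix shape {D.shape} != ({n}, {n})")
        if not np.all(np.isfinite(D)) or np.any(D < 0):
            raise ValueError("distances must be finite and nonnegative")
        if np.max(np.abs(D - D.T)) > 1e-9:
            raise ValueError("distance matrix must be symmetric")
        if np.max(np.abs(np.diag(D))) > 1e-9:
            raise ValueError("distance matrix must have zero diagonal")
        self.values = D

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.plant_ids, columns=self.plant_ids).to_csv(
            path, float_format="%.12g"
        )


@dataclass
class EmbeddingResult:
    """MDS coordinates (Geom1..Geomk), eigenvalues, positive-mass fraction."""

    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,), descending, all > 0
    positive_mass_fraction: float  # retained share of positive eigenvalue mass
    negative_mass: float  # total magnitude of discarded negative eigenvalues
    plant_ids: list[str] | None = None

    @property
    def column_names(self) -> list[str]:
        return [f"Geom{i + 1}" for i in range(self.coordinates.shape[1])]


def _resample_points(points: np.ndarray, m: int) -> np.ndarray:
    seg_len = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length curve")
    s = np.linspace(0.0, total, m)
    return np.column_stack([np.interp(s, cum, points[:, 0]),
                            np.interp(s, cum, points[:, 1])])


def resample_curve(curve: RootCurve, m: int) -> RootCurve:
    """Resample a polyline to ``m`` points equally spaced in arc length."""
    if m < 2:
        raise ValueError("m must be >= 2")
    return RootCurve(points=_resample_points(curve.points, m), order=curve.order,
                     parent_index=curve.parent_index,
                     attachment_arclength=curve.attachment_arclength)


def _anchored_resampled(system: RootSystem, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Seminal and lateral curves as (n, m, 2) arrays, seed at the origin."""
    seed = system.seed_point

    def stack(curves: list[RootCurve]) -> np.ndarray:
        if not curves:
            return np.zeros((0, m, 2))
        return np.stack([_resample_points(c.points, m) - seed for c in curves])

    return stack(system.seminal_curves), stack(system.lateral_curves)


def _set_cost(A: np.ndarray, B: np.ndarray) -> float:
    """Assignment cost between two curve sets given as (n, m, 2) arrays.

    The cost matrix holds RMS pointwise gaps; the matrix is padded to a
    square with each curve's RMS distance to the origin, so the assignment
    itself chooses which curves of the larger set go unmatched.
    """
    n1, n2 = A.shape[0], B.shape[0]
    if n1 == 0 and n2 == 0:
        return 0.0
    pen_a = np.sqrt(np.mean(np.sum(A**2, axis=2), axis=1)) if n1 else np.zeros(0)
    pen_b = np.sqrt(np.mean(np.sum(B**2, axis=2), axis=1)) if n2 else np.zeros(0)
    if n1 == 0:
        return float(pen_b.sum())
    if n2 == 0:
        return float(pen_a.sum())
    # mean_k |a_k - b_k|^2 = mean|a|^2 + mean|b|^2 - 2 mean(a.b), via one GEMM
    m = A.shape[1]
    gram = A.reshape(n1, -1) @ B.reshape(n2, -1).T / m
    scale = pen_a[:, None] ** 2 + pen_b[None, :] ** 2
    cost2 = scale - 2.0 * gram
    # dead-band at the cancellation noise floor so identical curves cost 0
    cost = np.sqrt(np.where(cost2 < 1e-12 * scale, 0.0, cost2))
    n = max(n1, n2)
    padded = np.zeros((n, n))
    padded[:n1, :n2] = cost
    if n1 < n2:
        padded[n1:, :n2] = pen_b[None, :]
    elif n2 < n1:
        padded[:n1, n2:] = pen_a[:, None]
    r, c = linear_sum_assignment(padded)
    return float(padded[r, c].sum())


def system_distance(
    a: RootSystem, b: RootSystem, params: DistanceParams = DistanceParams()
) -> float:
    """Distance between two root systems (see module docstring)."""
    params.validate()
    sa, la = _anchored_resampled(a, params.m)
    sb, lb = _anchored_resampled(b, params.m)
    return _set_cost(sa, sb) + params.lateral_weight * _set_cost(la, lb)


def distance_matrix(
    cohort: list[RootSystem], params: DistanceParams = DistanceParams()
) -> DistanceMatrix:
    """All pairwise root-system distances for a cohort."""
    params.validate()
    if len(cohort) < 2:
        raise ValueError("distance matrix needs at least 2 plants")
    pre = []
    for sys_ in cohort:
        try:
            pre.append(_anchored_resampled(sys_, params.m))
        except ValueError as e:
            raise ValueError(f"plant {sys_.plant_id}: {e}") from e
    n = len(cohort)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = (_set_cost(pre[i][0], pre[j][0])
                     + params.lateral_weight * _set_cost(pre[i][1], pre[j][1]))
            except Exception as e:  # keep plant ids in the error path
                raise ValueError(
                    f"distance failed for pair ({cohort[i].plant_id}, "
                    f"{cohort[j].plant_id}): {e}"
                ) from e
            D[i, j] = D[j, i] = d
    return DistanceMatrix(plant_ids=[s.plant_id for s in cohort], values=D, params=params)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each column positive."""
    out = coords.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


class ClassicalMDS(BaseEstimator):
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared distance matrix, B = -1/2 J D^2 J, and
    embeds with the top ``n_components`` eigenvectors scaled by the square
    roots of their (positive) eigenvalues.  On a Euclidean distance matrix
    of affine dimension <= n_components this reproduces the configuration
    exactly up to rigid motion.  Negative eigenvalues (from non-Euclidean
    input) are discarded and their total magnitude reported.

    Attributes (after fit): ``embedding_``, ``eigenvalues_``,
    ``positive_mass_fraction_``, ``negative_mass_``.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, D: DistanceMatrix | np.ndarray, y=None) -> "ClassicalMDS":
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        plant_ids = None
        if isinstance(D, DistanceMatrix):
            plant_ids = D.plant_ids
            Dm = D.values
        else:
            Dm = np.asarray(D, dtype=float)
        n = Dm.shape[0]
        if self.n_components > n - 1:
            raise ValueError("n_components must be <= n_plants - 1")
        D2 = Dm**2
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ D2 @ J
        B = (B + B.T) / 2.0
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        pos = w > 1e-12 * max(1.0, abs(w[0]))
        if pos[: self.n_components].sum() < self.n_components:
            raise ValueError(
                f"only {int(pos.sum())} positive eigenvalues; "
                f"reduce n_components from {self.n_components}"
            )
        k = self.n_components
        coords = _fix_signs(V[:, :k] * np.sqrt(w[:k]))
        pos_mass = float(w[pos].sum())
        self.embedding_ = coords
        self.eigenvalues_ = w[:k]
        self.positive_mass_fraction_ = float(w[:k].sum() / pos_mass) if pos_mass else 0.0
        self.negative_mass_ = float(-w[w < 0].sum())
        self.plant_ids_ = plant_ids
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_


def classical_mds(D: DistanceMatrix | np.ndarray, k: int = 5) -> EmbeddingResult:
    """Functional wrapper around :class:`ClassicalMDS`."""
    est = ClassicalMDS(n_components=k).fit(D)
    return EmbeddingResult(
        coordinates=est.embedding_,
        eigenvalues=est.eigenvalues_,
        positive_mass_fraction=est.positive_mass_fraction_,
        negative_mass=est.negative_mass_,
        plant_ids=est.plant_ids_,
    )
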