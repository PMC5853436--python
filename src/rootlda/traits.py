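"""Quantitative root-architecture traits and the plants x variables table.

Eleven geometry-derived traits are computed per plant (total length,
seminal tip/emergence angles, mean seminal and lateral lengths, root
counts, convex-hull area, maximum width and depth and their ratio), in the
style of the RootNav measurement suite, and combined with the five MDS
shape coordinates (Geom1-Geom5) into a 16-variable table that downstream
discriminant analyses consume after columnwise standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .rootgen import RootCurve, RootSystem

__all__ = [
    "TRAIT_NAMES",
    "GEOM_NAMES",
    "VARIABLE_NAMES",
    "META_COLUMNS",
    "TraitRecord",
    "TraitTable",
    "compute_traits",
    "build_trait_table",
    "standardize",
    "correlated_subset",
]

TRAIT_NAMES = (
    "TotalLength",
    "AvgSeminalTipAngle",
    "AvgSeminalEmergAngle",
    "AvgSeminalLength",
    "AvgLateralLength",
    "LateralCount",
    "SeminalCount",
    "ConvexHullArea",
    "MaxWidth",
    "MaxDepth",
    "WidthDepthRatio",
)
GEOM_NAMES = ("Geom1", "Geom2", "Geom3", "Geom4", "Geom5")
VARIABLE_NAMES = TRAIT_NAMES + GEOM_NAMES
META_COLUMNS = ("plant_id", "line", "nupe_class", "nitrate", "group_code")

#: Fraction of a seminal's arc length used for the emergence / tip chords.
ANGLE_WINDOW = 0.10


@dataclass(frozen=True)
class TraitRecord:
    """The 11 per-plant architecture traits (mm, mm^2, degrees, counts)."""

    total_length: float
    avg_seminal_tip_angle: float
    avg_seminal_emergence_angle: float
    avg_seminal_length: float
    avg_lateral_length: float
    lateral_count: int
    seminal_count: int
    convex_hull_area: float
    max_width: float
    max_depth: float
    width_depth_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([
            self.total_length, self.avg_seminal_tip_angle,
            self.avg_seminal_emergence_angle, self.avg_seminal_length,
            self.avg_lateral_length, float(self.lateral_count),
            float(self.seminal_count), self.convex_hull_area,
            self.max_width, self.max_depth, self.width_depth_ratio,
        ])


@dataclass
class TraitTable:
    """Plants x variables matrix with per-plant metadata.

    ``data`` is a DataFrame whose columns are the metadata columns followed
    by the trait/Geom variables; ``variables`` lists the numeric columns in
    canonical order.  ``standardized`` records whether each variable column
    has been scaled to mean 0 and sample variance 1.
    """

    data: pd.DataFrame
    variables: tuple[str, ...] = VARIABLE_NAMES
    standardized: bool = False

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        missing = [v for v in self.variables if v not in self.data.columns]
        if missing:
            raise ValueError(f"trait table is missing variable columns: {missing}")
        block = self.data[list(self.variables)]
        if block.isna().any().any():
            bad = block.columns[block.isna().any()].tolist()
            raise ValueError(f"trait table has missing cells in columns: {bad}")

    @property
    def values(self) -> np.ndarray:
        return self.data[list(self.variables)].to_numpy(dtype=float)

    @property
    def plant_ids(self) -> list[str]:
        return self.data["plant_id"].tolist()

    @property
    def n_plants(self) -> int:
        return len(self.data)

    def meta(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def subset(self, variables: list[str] | tuple[str, ...]) -> "TraitTable":
        """Restrict to a subset of variables, keeping metadata."""
        return TraitTable(
            data=self.data[[c for c in self.data.columns
                            if c in META_COLUMNS or c in variables]].copy(),
            variables=tuple(v for v in self.variables if v in set(variables)),
            standardized=self.standardized,
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.12g")


def _chord_angle_from_vertical(points: np.ndarray, window: float, end: str) -> float:
    """Unsigned angle (degrees) between a chord and the downward vertical.

    The chord spans the proximal (``end='start'``) or distal (``end='end'``)
    ``window`` fraction of the curve's arc length.
    """
    seg_len = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total == 0:
        return 0.0
    if end == "start":
        a, b = points[0], _interp_point(points, cum, window * total)
    else:
        a, b = _interp_point(points, cum, (1.0 - window) * total), points[-1]
    v = b - a
    norm = np.linalg.norm(v)
    if norm == 0:
        return 0.0
    cosang = np.clip(v[1] / norm, -1.0, 1.0)  # dot with (0, 1), y down
    return math.degrees(math.acos(cosang))


def _interp_point(points: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    x = np.interp(s, cum, points[:, 0])
    y = np.interp(s, cum, points[:, 1])
    return np.array([x, y])


def compute_traits(system: RootSystem, angle_window: float = ANGLE_WINDOW) -> TraitRecord:
    """Compute the 11 architecture traits for one root system.

    Angles are averaged over seminal roots only.  Depth is measured from
    the seed point (seeds sit at the top of the pouch), width is the
    horizontal extent over all curve points, and the hull area is the area
    of the 2-D convex hull of all points (0 if degenerate).
    """
    seminals = system.seminal_curves
    laterals = system.lateral_curves
    sem_lengths = [c.arc_length for c in seminals]
    lat_lengths = [c.arc_length for c in laterals]

    all_pts = np.vstack([c.points for c in system.curves])
    max_depth = float(np.max(all_pts[:, 1]) - system.seed_point[1])
    max_width = float(np.ptp(all_pts[:, 0]))
    try:
        hull_area = float(ConvexHull(all_pts).volume)  # 2-D: volume is area
    except QhullError:
        hull_area = 0.0

    emerg = [_chord_angle_from_vertical(c.points, angle_window, "start") for c in seminals]
    tip = [_chord_angle_from_vertical(c.points, angle_window, "end") for c in seminals]

    return TraitRecord(
        total_length=float(sum(sem_lengths) + sum(lat_lengths)),
        avg_seminal_tip_angle=float(np.mean(tip)),
        avg_seminal_emergence_angle=float(np.mean(emerg)),
        avg_seminal_length=float(np.mean(sem_lengths)),
        avg_lateral_length=float(np.mean(lat_lengths)) if lat_lengths else 0.0,
        lateral_count=len(laterals),
        seminal_count=len(seminals),
        convex_hull_area=hull_area,
        max_width=max_width,
        max_depth=max_depth,
        width_depth_ratio=max_width / max_depth if max_depth > 0 else 0.0,
    )


def build_trait_table(cohort: list[RootSystem], geom=None) -> TraitTable:
    """Assemble the unstandardized trait table for a cohort.

    ``geom`` is an EmbeddingResult (or plain array) whose rows must match
    the cohort order; when omitted, the table carries the 11 traits only.
    """
    rows = []
    for sys_ in cohort:
        rec = compute_traits(sys_)
        rows.append(
            dict(plant_id=sys_.plant_id, line=sys_.meta.line,
                 nupe_class=sys_.meta.nupe_class, nitrate=sys_.meta.nitrate,
                 group_code=sys_.meta.group_code,
                 **dict(zip(TRAIT_NAMES, rec.as_array()))),
        )
    df = pd.DataFrame(rows)
    variables: tuple[str, ...] = TRAIT_NAMES
    if geom is not None:
        coords = np.asarray(getattr(geom, "coordinates", geom), dtype=float)
        if coords.shape[0] != len(cohort):
            raise ValueError(
                f"geometry rows ({coords.shape[0]}) do not match cohort size ({len(cohort)})"
            )
        if coords.shape[1] != len(GEOM_NAMES):
            raise ValueError(
                f"expected {len(GEOM_NAMES)} Geom columns, got {coords.shape[1]}"
            )
        for j, name in enumerate(GEOM_NAMES):
            df[name] = coords[:, j]
        variables = VARIABLE_NAMES
    return TraitTable(data=df, variables=variables, standardized=False)


def standardize(table: TraitTable) -> TraitTable:
    """Scale every variable column to mean 0 and sample (N-1) variance 1."""
    if table.n_plants < 2:
        raise ValueError("standardization needs at least 2 plants")
    df = table.data.copy()
    for v in table.variables:
        col = df[v].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"variable {v!r} has zero variance; cannot standardize")
        df[v] = (col - col.mean()) / sd
    return TraitTable(data=df, variables=table.variables, standardized=True)


def correlated_subset(
    table: TraitTable, threshold: float = 0.5
) -> tuple[list[str], pd.DataFrame]:
    """Variables correlated (|r| >= threshold) with at least one other.

    Returns the retained variable names and the full Pearson correlation
    matrix rounded to two decimal places for display.  Pearson correlation
    is scale-invariant, so raw and standardized tables give the same answer.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    corr = pd.DataFrame(
        np.corrcoef(table.values, rowvar=False),
        index=table.variables, columns=table.variables,
    )
    off = corr.abs().to_numpy().copy()
    np.fill_diagonal(off, 0.0)
    keep = [v for v, m in zip(table.variables, off.max(axis=1)) if m >= threshold]
    return keep, corr.round(2)
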