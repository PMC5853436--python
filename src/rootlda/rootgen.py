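"""Synthetic 2-D seedling root systems with planted group differences.

Root systems are generated by a gravitropic correlated random walk: each
root grows as a chain of fixed-length segments whose heading relaxes toward
the downward vertical (image convention: y increases downward, seed at the
origin, angles in degrees from the downward vertical).  Lateral roots
emerge as a Poisson process along each seminal root beyond a basal offset
and grow by the same segment rule with their own parameters.

The generator's purpose is statistical, not botanical: it produces cohorts
whose trait distributions are shifted between groups (nitrogen-uptake-
efficiency class and nitrate treatment), so that the downstream distance /
MDS / discriminant / resampling stages can be exercised and calibrated
without the original growth-pouch data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RootCurve",
    "RootSystem",
    "PlantMeta",
    "GroupParams",
    "CohortSpec",
    "generate_root_system",
    "generate_cohort",
    "default_demo_spec",
    "group_code_for",
]

#: Group coding shared across the package: (nupe_class, nitrate) -> code.
GROUP_CODES = {
    ("low", "low"): 0,
    ("low", "high"): 1,
    ("high", "low"): 2,
    ("high", "high"): 3,
}


def group_code_for(nupe_class: str, nitrate: str) -> int:
    """Return the 0-3 group code for a (NUpE class, nitrate level) pair."""
    try:
        return GROUP_CODES[(nupe_class, nitrate)]
    except KeyError:
        raise ValueError(
            f"unknown (nupe_class, nitrate) combination: ({nupe_class!r}, {nitrate!r})"
        ) from None


@dataclass(frozen=True)
class PlantMeta:
    """Per-plant metadata: wheat line, NUpE class, nitrate treatment."""

    line: str
    nupe_class: str  # "low" | "high"
    nitrate: str  # "low" | "high"

    def __post_init__(self) -> None:
        if self.nupe_class not in ("low", "high"):
            raise ValueError(f"nupe_class must be 'low' or 'high', got {self.nupe_class!r}")
        if self.nitrate not in ("low", "high"):
            raise ValueError(f"nitrate must be 'low' or 'high', got {self.nitrate!r}")

    @property
    def group_code(self) -> int:
        return group_code_for(self.nupe_class, self.nitrate)


@dataclass(frozen=True)
class RootCurve:
    """One root as an ordered 2-D polyline (mm; y positive downward).

    Seminal roots have ``parent_index is None``; lateral roots reference the
    index of their parent seminal within the owning system's seminal list
    and record where along the parent (arc length, mm) they emerge.
    """

    points: np.ndarray  # (n, 2) float
    order: str  # "seminal" | "lateral"
    parent_index: int | None = None
    attachment_arclength: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("points must be an (n>=2, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("consecutive points must be distinct")
        if self.order not in ("seminal", "lateral"):
            raise ValueError(f"order must be 'seminal' or 'lateral', got {self.order!r}")
        if self.order == "lateral":
            if self.parent_index is None or self.attachment_arclength is None:
                raise ValueError("lateral curves need parent_index and attachment_arclength")

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass(frozen=True)
class RootSystem:
    """One plant: seed point plus its seminal and lateral root curves."""

    plant_id: str
    seed_point: np.ndarray  # (2,)
    curves: tuple[RootCurve, ...]
    meta: PlantMeta

    def __post_init__(self) -> None:
        sp = np.asarray(self.seed_point, dtype=float)
        object.__setattr__(self, "seed_point", sp)
        object.__setattr__(self, "curves", tuple(self.curves))
        seminals = self.seminal_curves
        if not seminals:
            raise ValueError(f"{self.plant_id}: a root system needs at least one seminal root")
        for c in seminals:
            if not np.allclose(c.points[0], sp, atol=1e-9):
                raise ValueError(f"{self.plant_id}: seminal roots must start at the seed point")
        n_sem = len(seminals)
        for c in self.lateral_curves:
            if not (0 <= c.parent_index < n_sem):
                raise ValueError(f"{self.plant_id}: lateral references missing seminal")
            parent_len = seminals[c.parent_index].arc_length
            if not (0.0 <= c.attachment_arclength <= parent_len + 1e-9):
                raise ValueError(f"{self.plant_id}: lateral attaches beyond its parent")

    @property
    def seminal_curves(self) -> list[RootCurve]:
        return [c for c in self.curves if c.order == "seminal"]

    @property
    def lateral_curves(self) -> list[RootCurve]:
        return [c for c in self.curves if c.order == "lateral"]


@dataclass(frozen=True)
class GroupParams:
    """Generator parameters for one NUpE x nitrate group.

    Lengths in mm, angles in degrees from the downward vertical.  Seminal
    and lateral lengths are log-normal (parameterized by log-mean/log-sd);
    headings evolve as ``theta <- (1 - g) * theta + noise`` with
    gravitropism weight ``g`` per 1 mm growth step.
    """

    seminal_count_mean: float = 5.0
    seminal_length_log_mean: float = math.log(120.0)
    seminal_length_log_sd: float = 0.25
    emergence_angle_mean: float = 25.0
    emergence_angle_sd: float = 10.0
    gravitropism: float = 0.05
    direction_noise_sd: float = 4.0
    lateral_density: float = 0.12  # emergences per mm of seminal root
    lateral_basal_offset: float = 10.0
    lateral_length_log_mean: float = math.log(8.0)
    lateral_length_log_sd: float = 0.45
    lateral_angle_mean: float = 60.0
    lateral_angle_sd: float = 12.0
    step: float = 1.0

    def validate(self) -> None:
        vals = {
            "seminal_count_mean": self.seminal_count_mean,
            "seminal_length_log_sd": self.seminal_length_log_sd,
            "emergence_angle_sd": self.emergence_angle_sd,
            "direction_noise_sd": self.direction_noise_sd,
            "lateral_density": self.lateral_density,
            "lateral_basal_offset": self.lateral_basal_offset,
            "lateral_length_log_sd": self.lateral_length_log_sd,
            "lateral_angle_sd": self.lateral_angle_sd,
            "step": self.step,
        }
        for name, v in vals.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if not math.isfinite(self.seminal_length_log_mean) or not math.isfinite(
            self.lateral_length_log_mean
        ):
            raise ValueError("length log-means must be finite")
        if not (0.0 <= self.gravitropism <= 1.0):
            raise ValueError("gravitropism weight must be in [0, 1]")
        for name, a in (
            ("emergence_angle_mean", self.emergence_angle_mean),
            ("lateral_angle_mean", self.lateral_angle_mean),
        ):
            if not (0.0 <= a < 180.0):
                raise ValueError(f"{name} must be in [0, 180), got {a}")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: per-cell plant counts plus per-group generator params.

    ``cells`` entries are (line, nupe_class, nitrate, n_plants);
    ``group_params`` maps group code 0-3 to the parameters used for every
    plant in that group.
    """

    cells: tuple[tuple[str, str, str, int], ...]
    group_params: dict[int, GroupParams] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(tuple(c) for c in self.cells))
        for line, nupe, nitrate, n in self.cells:
            group_code_for(nupe, nitrate)
            if n < 0:
                raise ValueError(f"cell ({line}, {nupe}, {nitrate}): n_plants must be >= 0")
        for code, gp in self.group_params.items():
            if code not in (0, 1, 2, 3):
                raise ValueError(f"group code must be 0-3, got {code}")
            gp.validate()


def _grow_chain(
    start: np.ndarray,
    theta0: float,
    total_length: float,
    gravitropism: float,
    noise_sd: float,
    step: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow a segment chain from ``start`` with initial heading ``theta0``.

    Headings are angles (radians) from the downward vertical; each step
    relaxes toward 0 by the gravitropism weight and adds Gaussian noise.
    The final segment is shortened so total arc length equals
    ``total_length`` exactly.
    """
    n_full, rem = divmod(total_length, step)
    n_full = int(n_full)
    lengths = [step] * n_full
    if rem > 1e-12:
        lengths.append(rem)
    if not lengths:  # degenerate draw below one step
        lengths = [max(total_length, 1e-6)]
    pts = np.empty((len(lengths) + 1, 2))
    pts[0] = start
    theta = theta0
    for i, ell in enumerate(lengths):
        pts[i + 1] = pts[i] + ell * np.array([math.sin(theta), math.cos(theta)])
        theta = (1.0 - gravitropism) * theta + rng.normal(0.0, math.radians(noise_sd))
    return pts


def _point_and_heading_at(points: np.ndarray, s: float) -> tuple[np.ndarray, float]:
    """Point on a polyline at arc length ``s`` and the local heading angle."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(i, len(seg) - 1)
    frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    pt = points[i] + frac * seg[i]
    heading = math.atan2(seg[i, 0], seg[i, 1])  # angle from downward vertical
    return pt, heading


def generate_root_system(
    params: GroupParams,
    rng: np.random.Generator,
    plant_id: str = "plant",
    meta: PlantMeta | None = None,
) -> RootSystem:
    """Generate one plant's root system from a group parameter set.

    Seminal count is Poisson with the given mean, truncated to >= 1.
    Each seminal starts at the seed point (origin) with a signed emergence
    angle drawn from a normal, grows as a gravitropic correlated random
    walk until its drawn log-normal length is reached.  Lateral emergence
    points follow a Poisson process along each seminal beyond the basal
    offset; each lateral branches off at +/- its branch angle relative to
    the parent's local heading.
    """
    params.validate()
    if meta is None:
        meta = PlantMeta(line="synthetic", nupe_class="low", nitrate="low")
    seed = np.zeros(2)

    n_sem = max(1, int(rng.poisson(params.seminal_count_mean)))
    curves: list[RootCurve] = []
    seminal_pts: list[np.ndarray] = []
    for _ in range(n_sem):
        length = float(rng.lognormal(params.seminal_length_log_mean, params.seminal_length_log_sd))
        angle = rng.normal(params.emergence_angle_mean, params.emergence_angle_sd)
        angle = math.copysign(min(abs(angle), 179.0), angle)
        theta0 = math.radians(angle) * (1 if rng.random() < 0.5 else -1)
        pts = _grow_chain(seed, theta0, length, params.gravitropism,
                          params.direction_noise_sd, params.step, rng)
        seminal_pts.append(pts)
        curves.append(RootCurve(points=pts, order="seminal"))

    for parent_idx, ppts in enumerate(seminal_pts):
        parent_len = float(np.sum(np.linalg.norm(np.diff(ppts, axis=0), axis=1)))
        span = parent_len - params.lateral_basal_offset
        if span <= 0 or params.lateral_density == 0:
            continue
        n_lat = int(rng.poisson(params.lateral_density * span))
        if n_lat == 0:
            continue
        positions = np.sort(params.lateral_basal_offset + span * rng.random(n_lat))
        for s in positions:
            origin, heading = _point_and_heading_at(ppts, float(s))
            branch = rng.normal(params.lateral_angle_mean, params.lateral_angle_sd)
            branch = math.copysign(min(abs(branch), 179.0), branch)
            theta0 = heading + math.radians(branch) * (1 if rng.random() < 0.5 else -1)
            length = float(
                rng.lognormal(params.lateral_length_log_mean, params.lateral_length_log_sd)
            )
            pts = _grow_chain(origin, theta0, length, params.gravitropism,
                              params.direction_noise_sd, params.step, rng)
            curves.append(
                RootCurve(points=pts, order="lateral",
                          parent_index=parent_idx, attachment_arclength=float(s))
            )

    return RootSystem(plant_id=plant_id, seed_point=seed, curves=tuple(curves), meta=meta)


def generate_cohort(spec: CohortSpec) -> list[RootSystem]:
    """Generate a full cohort of root systems from a cohort spec.

    Each plant draws from its own counter-based substream (SeedSequence
    spawn key = global plant index), so per-plant generation is independent
    of order and the cohort is bit-reproducible for a given rng_seed.
    """
    systems: list[RootSystem] = []
    seen: set[str] = set()
    plant_index = 0
    for line, nupe, nitrate, n in spec.cells:
        code = group_code_for(nupe, nitrate)
        gp = spec.group_params.get(code, GroupParams())
        meta = PlantMeta(line=line, nupe_class=nupe, nitrate=nitrate)
        for j in range(n):
            pid = f"{line}_{'N+' if nitrate == 'high' else 'N-'}_{j:03d}"
            if pid in seen:
                raise ValueError(f"duplicate plant_id {pid}")
            seen.add(pid)
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.rng_seed, spawn_key=(plant_index,))
            )
            systems.append(generate_root_system(gp, rng, plant_id=pid, meta=meta))
            plant_index += 1
    return systems


# Nine wheat lines; four low-NUpE, five high-NUpE.  One cell (W199 at high
# nitrate) is absent, leaving 17 line x treatment cells.
LOW_NUPE_LINES = ("W145", "W199", "W325", "W705")
HIGH_NUPE_LINES = ("W149", "W483", "W637", "W685", "W700")
MISSING_CELL = ("W199", "high")


def _default_group_params() -> dict[int, GroupParams]:
    """Planted effect profile.

    The NUpE-class contrast is the dominant effect: low-NUpE plants have
    shorter seminal roots and sparser laterals (about one within-group sd
    on each).  The nitrate contrast is smaller and is larger within the
    low-NUpE groups than within the high-NUpE groups, so that the relative
    strengths of the block-permutation tests mirror the study design.
    """
    base = GroupParams()
    # seminal_length_log_sd = 0.25, so a 0.25 log-mean shift is ~1 within-group sd;
    # lateral density shifts are ~1 sd of the per-plant lateral count.
    return {
        0: replace(base, seminal_length_log_mean=math.log(120.0) - 0.25,
                   lateral_density=0.085, emergence_angle_mean=30.0),
        1: replace(base, seminal_length_log_mean=math.log(120.0) - 0.37,
                   lateral_density=0.10, emergence_angle_mean=24.0),
        2: replace(base, seminal_length_log_mean=math.log(120.0),
                   lateral_density=0.12, emergence_angle_mean=25.0),
        3: replace(base, seminal_length_log_mean=math.log(120.0) - 0.04,
                   lateral_density=0.125, emergence_angle_mean=23.0),
    }


def default_demo_spec(rng_seed: int = 0, n_per_cell: int = 17) -> CohortSpec:
    """The demo cohort: 9 lines x 2 nitrate levels minus one absent cell.

    With the default 17 plants per cell this gives 17 cells and 289 plants,
    the approximate size of the study cohort.
    """
    cells = []
    for line in LOW_NUPE_LINES + HIGH_NUPE_LINES:
        nupe = "low" if line in LOW_NUPE_LINES else "high"
        for nitrate in ("low", "high"):
            if (line, nitrate) == MISSING_CELL:
                continue
            cells.append((line, nupe, nitrate, n_per_cell))
    return CohortSpec(cells=tuple(cells), group_params=_default_group_params(),
                      rng_seed=rng_seed)


def null_demo_spec(rng_seed: int = 0, n_per_cell: int = 17) -> CohortSpec:
    """Same design as the demo spec but with no group differences."""
    spec = default_demo_spec(rng_seed=rng_seed, n_per_cell=n_per_cell)
    return CohortSpec(cells=spec.cells,
                      group_params={c: GroupParams() for c in range(4)},
                      rng_seed=rng_seed)
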