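import numpy as np
import pytest

from rootlda.rootgen import (
    CohortSpec,
    GroupParams,
    PlantMeta,
    RootCurve,
    RootSystem,
    default_demo_spec,
    generate_cohort,
)


def make_system(curves, plant_id="p", line="W145", nupe="low", nitrate="low"):
    return RootSystem(
        plant_id=plant_id,
        seed_point=np.zeros(2),
        curves=tuple(curves),
        meta=PlantMeta(line=line, nupe_class=nupe, nitrate=nitrate),
    )


def vertical_system(length=100.0, plant_id="p", **kw):
    """One straight vertical seminal of the given length, no laterals."""
    pts = np.array([[0.0, 0.0], [0.0, length / 2], [0.0, length]])
    return make_system([RootCurve(points=pts, order="seminal")], plant_id=plant_id, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """17-cell demo cohort, 3 plants per cell (fast, fixed seed)."""
    return generate_cohort(default_demo_spec(rng_seed=11, n_per_cell=3))


@pytest.fixture(scope="session")
def grouped_data():
    """Random 4-group data with planted mean separation (N=80, p=5)."""
    rng = np.random.default_rng(42)
    n_per, p = 20, 5
    shifts = np.array([[0, 0, 0, 0, 0], [1.5, 0, 0, 0, 0],
                       [0, 1.5, 0, 0, 0], [1.0, 1.0, 0, 0, 0]], dtype=float)
    X = np.vstack([rng.normal(size=(n_per, p)) + s for s in shifts])
    labels = np.repeat([0, 1, 2, 3], n_per)
    return X, labels


@pytest.fixture(scope="session")
def tiny_spec():
    cells = (
        ("A", "low", "low", 2),
        ("A", "low", "high", 2),
        ("B", "high", "low", 2),
    )
    return CohortSpec(cells=cells, group_params={0: GroupParams()}, rng_seed=5)
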