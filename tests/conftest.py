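import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from shapely.geometry import Point

from mangroveprio import (
    ProblemInstance,
    SeascapeConfig,
    generate_seascape,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-unit, 8-species seascape reused across read-only tests."""
    return generate_seascape(
        SeascapeConfig(n_units=60, n_species=8, n_provinces=3, n_zones=4, seed=11)
    )


@pytest.fixture(scope="session")
def small_labels(small_dataset):
    units = small_dataset.units
    typ = dict(zip(units["id"].astype(int), units["typology_id"].astype(int)))
    prov = dict(zip(units["id"].astype(int), units["province_id"].astype(int)))
    return typ, prov


def point_units(xs, areas=None, **extra):
    """Minimal units table with point geometries for hand-built examples."""
    n = len(xs)
    frame = {
        "id": np.arange(n),
        "geometry": [Point(x, 0.0) for x in xs],
        "mangrove_area_km2": np.ones(n) if areas is None else np.asarray(areas, dtype=float),
    }
    frame.update(extra)
    return pd.DataFrame(frame)


def random_problem(seed, max_units=12):
    """Random feasible minimum-shortfall instance (solver-oracle tests)."""
    rng = np.random.default_rng(seed)
    while True:
        n = int(rng.integers(4, max_units + 1))
        f = int(rng.integers(5, 31))
        dense = rng.random((f, n)) * (rng.random((f, n)) < 0.5)
        totals = dense.sum(axis=1)
        if np.all(totals > 0):
            break
    targets = totals * rng.uniform(0.1, 0.9, f)
    weights = rng.uniform(0.5, 2.0, f)
    costs = rng.uniform(0.5, 2.0, n)
    budget = costs.sum() * rng.uniform(0.2, 0.8)
    locked = frozenset()
    if rng.random() < 0.3:
        j = int(rng.integers(0, n))
        if costs[j] <= budget:
            locked = frozenset({j})
    return ProblemInstance(
        sparse.csr_matrix(dense),
        targets,
        weights,
        costs,
        np.arange(n),
        [f"f{i}" for i in range(f)],
        locked,
        float(budget),
    )


def three_unit_problem(locked=frozenset(), budget=1.0):
    """One feature with amounts (0.6, 0.3, 0.1), target 0.5, unit costs."""
    return ProblemInstance(
        sparse.csr_matrix(np.array([[0.6, 0.3, 0.1]])),
        np.array([0.5]),
        np.array([1.0]),
        np.ones(3),
        np.arange(3),
        ["f0"],
        frozenset(locked),
        float(budget),
    )
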