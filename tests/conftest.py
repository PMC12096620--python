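import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by integration-level tests."""
    from tmahet import synthetic

    spec = synthetic.CohortSpec(
        n_cases=4,
        regions_per_case_range=(2, 3),
        cells_per_core_range=(250, 400),
        seed=42,
    )
    tables, metadata, truth = synthetic.simulate_cohort(spec)
    return tables, metadata, truth


@pytest.fixture()
def cell_table_3():
    """Minimal valid 3-cell IHC4 table."""
    return pd.DataFrame({
        "cell_id": ["c1", "c2", "c3"],
        "case_id": ["L01"] * 3,
        "core_id": ["L01_R1"] * 3,
        "x": [10.0, 20.0, 30.0],
        "y": [5.0, 6.0, 7.0],
        "area": [100.0, 110.0, 120.0],
        "DAPI": [2000.0, 2500.0, 3000.0],
        "ER": [100.0, 200.0, 300.0],
        "PR": [50.0, 60.0, 70.0],
        "HER2": [80.0, 90.0, 100.0],
        "Ki67": [10.0, 20.0, 30.0],
        "CK8_18": [500.0, 600.0, 700.0],
    })


def brute_force_modularity(graph, labels):
    """Independent O(n^2) modularity: Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ."""
    n = graph.vcount()
    A = np.zeros((n, n))
    w = graph.es["weight"] if "weight" in graph.es.attributes() else [1.0] * graph.ecount()
    for e, wt in zip(graph.get_edgelist(), w):
        A[e[0], e[1]] += wt
        A[e[1], e[0]] += wt
    k = A.sum(axis=1)
    two_m = A.sum()
    labels = np.asarray(labels)
    delta = labels[:, None] == labels[None, :]
    return float(((A - np.outer(k, k) / two_m) * delta).sum() / two_m)


def brute_force_rao(proportions, d=None):
    """Independent Rao quadratic entropy: Σ_i Σ_j p_i p_j d_ij."""
    p = np.asarray(proportions, dtype=float)
    if d is None:
        d = 1.0 - np.eye(len(p))
    return float(sum(p[i] * p[j] * d[i, j]
                     for i in range(len(p)) for j in range(len(p))))
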