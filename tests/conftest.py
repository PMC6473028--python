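import numpy as np
import pandas as pd
import pytest

from metabnet.roi_io import RoiSignalTable, default_atlas
from metabnet.synthetic import (
    CohortConfig,
    default_cohort_config,
    default_structure,
    generate_cohort,
)


def random_graph(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """A random symmetric 0/1 adjacency with zero diagonal (5-12 nodes)."""
    if n is None:
        n = int(rng.integers(5, 13))
    p = rng.uniform(0.2, 0.7)
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


def graph_from_edges(n: int, edges: list[tuple[int, int]]) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


def make_table(signals: np.ndarray, group: str = "G",
               age: np.ndarray | None = None,
               sex: np.ndarray | None = None,
               roi_names: list[str] | None = None) -> RoiSignalTable:
    """Wrap a raw signal matrix in a RoiSignalTable with covariate columns."""
    n, r = signals.shape
    if roi_names is None:
        roi_names = [f"ROI{i}" for i in range(r)]
    df = pd.DataFrame(signals, columns=roi_names)
    df.insert(0, "sex", sex if sex is not None else np.arange(n) % 2)
    df.insert(0, "age", age if age is not None else np.linspace(55, 75, n))
    df.insert(0, "group", group)
    df.insert(0, "subject_id", [f"{group}_{i}" for i in range(n)])
    return RoiSignalTable(df, roi_names=roi_names)


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def base_structure():
    return default_structure()


@pytest.fixture(scope="session")
def small_cohort():
    """Four small groups from the default study layout (seeded)."""
    return generate_cohort(default_cohort_config(seed=11))


@pytest.fixture(scope="session")
def big_hc_table(base_structure):
    """One large symmetric-structure group for recovery-style checks."""
    cfg = CohortConfig(
        group_specs=(("HC", 200),), network_spec={"HC": base_structure}, seed=5
    )
    return generate_cohort(cfg).tables["HC"]
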