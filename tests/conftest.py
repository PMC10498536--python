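import numpy as np
import pytest

import sconet as sc


def adjacency_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


@pytest.fixture(scope="session")
def planted_table():
    """Residualized two-group morphometry with a planted topology difference."""
    high, low = sc.scenario_configs("planted", seed=11)
    return sc.residualize(sc.generate_morphometry(high, low, seed=11))


@pytest.fixture(scope="session")
def null_table():
    """Residualized two-group morphometry with no group difference."""
    high, low = sc.scenario_configs("null", seed=12)
    return sc.residualize(sc.generate_morphometry(high, low, seed=12))


def assignment_from(table):
    return sc.GroupAssignment(
        high_group={s for s, g in zip(table.subjects, table.group) if g == "high"},
        low_group={s for s, g in zip(table.subjects, table.group) if g == "low"},
    )


@pytest.fixture(scope="session")
def planted_assignment(planted_table):
    return assignment_from(planted_table)


@pytest.fixture(scope="session")
def null_assignment(null_table):
    return assignment_from(null_table)
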