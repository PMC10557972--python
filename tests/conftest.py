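import numpy as np
import pandas as pd
import pytest

from aedplace.geometry import CandidateSet, DemandPoint, HourlyDemand, coverage_sets
from aedplace.mclp import MCLPInstance
from aedplace.synth import generate_worked_example


@pytest.fixture
def toy_candidates() -> CandidateSet:
    """C1(5,0), C2(205,0), C3(500,0) on a line."""
    return CandidateSet(["C1", "C2", "C3"],
                        np.array([5.0, 205.0, 500.0]),
                        np.array([0.0, 0.0, 0.0]))


@pytest.fixture
def toy_demand() -> HourlyDemand:
    """P1(0,0), P2(10,0), P3(200,0), P4(210,0), unit weights."""
    return HourlyDemand(0, [DemandPoint("P1", 0, 0), DemandPoint("P2", 10, 0),
                            DemandPoint("P3", 200, 0), DemandPoint("P4", 210, 0)])


@pytest.fixture
def worked_example():
    return generate_worked_example()


def random_instance(rng: np.random.Generator, n_i_max: int = 30,
                    n_j_max: int = 10, k_max: int = 3,
                    unit_weights: bool = False):
    """A random MCLP instance small enough for exhaustive enumeration."""
    n_i = int(rng.integers(1, n_i_max + 1))
    n_j = int(rng.integers(1, n_j_max + 1))
    k = int(rng.integers(1, min(k_max, n_j) + 1))
    di = rng.uniform(0, 1000, size=(n_i, 2))
    dj = rng.uniform(0, 1000, size=(n_j, 2))
    weights = (np.ones(n_i) if unit_weights
               else rng.uniform(0.1, 10.0, size=n_i))
    demand = HourlyDemand(0, [DemandPoint(f"p{i}", di[i, 0], di[i, 1], weights[i])
                              for i in range(n_i)])
    candidates = CandidateSet([f"c{j}" for j in range(n_j)], dj[:, 0], dj[:, 1])
    S = float(rng.uniform(50, 500))
    return MCLPInstance(demand, candidates, coverage_sets(demand, candidates, S), k), S
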