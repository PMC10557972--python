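"""Maximal covering location problem (MCLP) solvers and coverage evaluation.

Choose ``k`` facility sites from candidates ``J`` maximizing the demand
weight covered within service distance ``S``:

    maximize   z = sum_i a_i * y_i
    subject to sum_{j in N_i} x_j >= y_i   for all demand points i
               sum_j x_j = k
               x_j, y_i binary

Three solution routes are provided: an exact integer program (HiGHS
branch-and-bound via :func:`scipy.optimize.milp`, optimality gap 0), the
classic greedy maximum-coverage heuristic with its (1 - 1/e) guarantee,
and exhaustive enumeration as a test oracle for small instances.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .geometry import CandidateSet, CoverageStructure, HourlyDemand, coverage_sets

__all__ = [
    "MCLPInstance",
    "MCLPSolution",
    "CoverageEvaluation",
    "solve_exact",
    "solve_greedy",
    "solve_bruteforce",
    "evaluate_coverage",
]

# enumeration cap when canonicalizing exact-solver ties
_CANONICAL_MAX_COMBINATIONS = 20_000


@dataclass
class MCLPInstance:
    """One period's MCLP: demand, candidates, coverage structure, budget ``k``."""

    demand: HourlyDemand
    candidates: CandidateSet
    coverage: CoverageStructure
    k: int

    def __post_init__(self) -> None:
        if len(self.candidates) == 0:
            raise ValueError("instance requires at least one candidate site")
        if not (1 <= self.k <= len(self.candidates)):
            raise ValueError(f"budget k={self.k} must be in [1, {len(self.candidates)}]")
        missing = set(i for i in self.demand.ids()) - set(self.coverage.cover_sets)
        if missing:
            raise ValueError(f"coverage structure lacks demand ids: {sorted(map(str, missing))[:5]}")

    @classmethod
    def build(cls, demand: HourlyDemand, candidates: CandidateSet,
              S: float, k: int) -> "MCLPInstance":
        cov = (coverage_sets(demand, candidates, S) if len(demand)
               else CoverageStructure(S, {}))
        return cls(demand, candidates, cov, k)


@dataclass
class MCLPSolution:
    """A selected site set with its per-point coverage indicators and objective."""

    chosen: frozenset
    covered: dict
    objective: float
    method: str
    optimal: bool
    k: int
    canonical: bool = True
    period: int | None = None

    @property
    def chosen_sorted(self) -> list:
        return sorted(self.chosen, key=_id_key)


@dataclass
class CoverageEvaluation:
    """Coverage of one demand set by an arbitrary site set (indicators ``O_i``)."""

    covered_indicator: dict
    covered_weight: float
    total_weight: float
    rate: float


def _id_key(sid):
    return (str(type(sid).__name__), sid) if not isinstance(sid, str) else ("str", sid)


def _sorted_ids(ids) -> list:
    return sorted(ids, key=_id_key)


def _aggregate(instance: MCLPInstance):
    """Group demand points by identical cover set; drop uncoverable ones.

    Returns (unique cover sets as candidate-index lists, aggregated weights).
    Points with empty N_i cannot be covered and contribute nothing to the
    objective, but remain in the instance's totals.
    """
    cand_index = {sid: j for j, sid in enumerate(instance.candidates.ids)}
    groups: dict[frozenset, float] = {}
    for p in instance.demand.points:
        ni = instance.coverage.cover_sets[p.id]
        if ni:
            groups[ni] = groups.get(ni, 0.0) + p.weight
    sets = [np.array([cand_index[s] for s in ni], dtype=int) for ni in groups]
    weights = np.array(list(groups.values()), dtype=float)
    return sets, weights


def _mk_solution(instance: MCLPInstance, chosen, method: str, optimal: bool,
                 canonical: bool = True) -> MCLPSolution:
    chosen = frozenset(chosen)
    covered = {p.id: int(bool(instance.coverage.cover_sets[p.id] & chosen))
               for p in instance.demand.points}
    objective = float(sum(p.weight for p in instance.demand.points if covered[p.id]))
    return MCLPSolution(chosen, covered, objective, method, optimal,
                        instance.k, canonical, instance.demand.period)


def _empty_demand_solution(instance: MCLPInstance, method: str) -> MCLPSolution:
    warnings.warn("empty demand: returning the k lexicographically smallest sites "
                  "with objective 0", stacklevel=3)
    chosen = _sorted_ids(instance.candidates.ids)[: instance.k]
    return MCLPSolution(frozenset(chosen), {}, 0.0, method, True, instance.k,
                        True, instance.demand.period)


def _objective_of(sets, weights, chosen_idx: set) -> float:
    return float(sum(w for s, w in zip(sets, weights)
                     if not chosen_idx.isdisjoint(s)))


def solve_exact(instance: MCLPInstance) -> MCLPSolution:
    """Provably optimal MCLP solution via mixed-integer programming.

    Demand points sharing an identical coverable-site set are aggregated
    into one binary coverage variable (their weights add in the objective),
    which leaves the optimum unchanged.  Among equally optimal site sets
    the lexicographically smallest is reported when exhaustive enumeration
    is affordable; otherwise the solver incumbent is returned with
    ``canonical=False``.
    """
    if len(instance.demand) == 0:
        return _empty_demand_solution(instance, "exact")
    sets, weights = _aggregate(instance)
    n_j = len(instance.candidates)
    n_y = len(sets)
    if n_y == 0:
        # nothing coverable: any k sites are optimal; report canonical set
        chosen = _sorted_ids(instance.candidates.ids)[: instance.k]
        return _mk_solution(instance, chosen, "exact", True)

    # variables: x_0..x_{n_j-1}, y_0..y_{n_y-1}
    c = np.concatenate([np.zeros(n_j), -weights])
    rows, cols, vals = [], [], []
    for r, s in enumerate(sets):
        rows.append(r); cols.append(n_j + r); vals.append(1.0)
        for j in s:
            rows.append(r); cols.append(int(j)); vals.append(-1.0)
    a_cov = sparse.csr_matrix((vals, (rows, cols)), shape=(n_y, n_j + n_y))
    cov_con = LinearConstraint(a_cov, -np.inf, 0.0)
    a_bud = sparse.csr_matrix(
        (np.ones(n_j), (np.zeros(n_j, dtype=int), np.arange(n_j))),
        shape=(1, n_j + n_y))
    bud_con = LinearConstraint(a_bud, instance.k, instance.k)
    res = milp(c, constraints=[cov_con, bud_con],
               integrality=np.ones(n_j + n_y),
               bounds=Bounds(0, 1),
               options={"mip_rel_gap": 0.0})
    if res.status != 0:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    x = res.x[:n_j]
    chosen_idx = [j for j in range(n_j) if x[j] > 0.5]
    # HiGHS may leave slack if fewer than k sites are useful; pad canonically
    chosen_idx = _pad_to_k(chosen_idx, instance)
    best_obj = _objective_of(sets, weights, set(chosen_idx))

    canonical = False
    n_comb = math.comb(n_j, instance.k)
    if n_comb <= _CANONICAL_MAX_COMBINATIONS:
        chosen_idx = _lex_smallest_optimal(instance, sets, weights, best_obj)
        canonical = True
    chosen = [instance.candidates.ids[j] for j in chosen_idx]
    sol = _mk_solution(instance, chosen, "exact", True, canonical)
    assert abs(sol.objective - best_obj) < 1e-6 * max(1.0, abs(best_obj))
    return sol


def _pad_to_k(chosen_idx: list[int], instance: MCLPInstance) -> list[int]:
    if len(chosen_idx) >= instance.k:
        return chosen_idx[: instance.k]
    order = sorted(range(len(instance.candidates)),
                   key=lambda j: _id_key(instance.candidates.ids[j]))
    have = set(chosen_idx)
    extra = [j for j in order if j not in have]
    return chosen_idx + extra[: instance.k - len(chosen_idx)]


def _lex_smallest_optimal(instance, sets, weights, best_obj) -> list[int]:
    """First k-subset (in lexicographic id order) attaining the optimum."""
    order = sorted(range(len(instance.candidates)),
                   key=lambda j: _id_key(instance.candidates.ids[j]))
    for combo in itertools.combinations(order, instance.k):
        if _objective_of(sets, weights, set(combo)) >= best_obj - 1e-9:
            return list(combo)
    raise AssertionError("optimum not re-attained during canonicalization")


def solve_greedy(instance: MCLPInstance) -> MCLPSolution:
    """Greedy maximum-marginal-coverage heuristic.

    Runs ``k`` iterations, each adding the candidate covering the most
    yet-uncovered weight (ties to the lexicographically smallest id).  By
    submodularity the objective is at least ``(1 - 1/e)`` of the optimum.
    """
    if len(instance.demand) == 0:
        return _empty_demand_solution(instance, "greedy")
    sets, weights = _aggregate(instance)
    n_j = len(instance.candidates)
    # marginal gain bookkeeping: which aggregated groups each candidate covers
    covers_of_j: list[list[int]] = [[] for _ in range(n_j)]
    for g, s in enumerate(sets):
        for j in s:
            covers_of_j[int(j)].append(g)
    gain = np.zeros(n_j)
    for j in range(n_j):
        gain[j] = weights[covers_of_j[j]].sum() if covers_of_j[j] else 0.0
    alive = np.ones(len(sets), dtype=bool)
    id_order = [_id_key(s) for s in instance.candidates.ids]
    chosen_idx: list[int] = []
    available = set(range(n_j))
    for _ in range(instance.k):
        best_j = min(available, key=lambda j: (-gain[j], id_order[j]))
        chosen_idx.append(best_j)
        available.discard(best_j)
        newly = [g for g in covers_of_j[best_j] if alive[g]]
        for g in newly:
            alive[g] = False
            for j in sets[g]:
                gain[int(j)] -= weights[g]
    chosen = [instance.candidates.ids[j] for j in chosen_idx]
    return _mk_solution(instance, chosen, "greedy", False)


def solve_bruteforce(instance: MCLPInstance,
                     max_combinations: int = 200_000) -> MCLPSolution:
    """Exhaustive enumeration of all k-subsets (test oracle).

    Candidates are enumerated in lexicographic id order, so the first
    subset attaining the maximum is the lexicographically smallest —
    the same canonical tie-break as :func:`solve_exact`.
    """
    if len(instance.demand) == 0:
        return _empty_demand_solution(instance, "brute_force")
    n_j = len(instance.candidates)
    n_comb = math.comb(n_j, instance.k)
    if n_comb > max_combinations:
        raise ValueError(f"C({n_j},{instance.k}) = {n_comb} exceeds "
                         f"max_combinations = {max_combinations}")
    sets, weights = _aggregate(instance)
    order = sorted(range(n_j), key=lambda j: _id_key(instance.candidates.ids[j]))
    best_combo, best_obj = None, -1.0
    for combo in itertools.combinations(order, instance.k):
        obj = _objective_of(sets, weights, set(combo))
        if obj > best_obj + 1e-12:
            best_combo, best_obj = combo, obj
    chosen = [instance.candidates.ids[j] for j in best_combo]
    return _mk_solution(instance, chosen, "brute_force", True)


def evaluate_coverage(sites, demand: HourlyDemand, candidates: CandidateSet,
                      S: float) -> CoverageEvaluation:
    """Coverage of ``demand`` by the given site ids at service distance ``S``.

    ``O_i = 1`` iff the nearest chosen site is within ``S`` (inclusive);
    the rate is covered weight over total weight.  An empty demand set is
    vacuously covered (rate 1.0, with a warning).
    """
    sites = list(sites)
    unknown = set(sites) - set(candidates.ids)
    if unknown:
        raise KeyError(f"unknown site id(s): {sorted(map(str, unknown))}")
    if len(demand) == 0:
        warnings.warn("empty demand: coverage rate is vacuously 1.0", stacklevel=2)
        return CoverageEvaluation({}, 0.0, 0.0, 1.0)
    chosen = candidates.subset(sites)
    di = demand.coords()
    dj = chosen.coords()
    if len(sites) == 0:
        o = np.zeros(len(demand), dtype=bool)
    else:
        d = np.hypot(di[:, 0:1] - dj[None, :, 0], di[:, 1:2] - dj[None, :, 1])
        o = d.min(axis=1) <= S
    w = demand.weights()
    covered_weight = float(w[o].sum())
    total = float(w.sum())
    rate = covered_weight / total if total > 0 else 1.0
    indicator = {pid: int(v) for pid, v in zip(demand.ids(), o)}
    return CoverageEvaluation(indicator, covered_weight, total, rate)
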