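"""Flux-sum scan workflow: from a model to a ranked list of metabolite targets.

The procedure, per scanned metabolite i and perturbation level k in [0, 1]:

1. *Reference state.*  Maximize biomass; with biomass pinned, optimize the
   target exchange in the goal-adverse sense (worst case) to pick one
   well-defined wild-type vertex.  Phi_WT of every candidate metabolite is
   evaluated at that vertex.
2. *Turnover range.*  Solve the two extremum MILPs for (Phi_min, Phi_max).
3. *Growth under perturbation.*  Maximize biomass subject to one of

       (C1, attenuation)      Phi_i <= Phi_min + k * (Phi_WT - Phi_min)
       (C2, intensification)  Phi_i >= Phi_WT  + k * (Phi_max - Phi_WT)

   giving the guaranteed-attainable growth B_ik.
4. *Worst-case production.*  With v_biomass >= B_ik, optimize the target
   exchange adversely again.  A metabolite is a target when some point's
   worst-case production improves on the wild type in the goal direction.

Attenuation k runs from the turnover minimum (k=0) up to the wild type
(k=1); intensification runs from the wild type (k=0) up to the maximum
(k=1), so the k=1 / k=0 endpoints respectively reproduce the reference
state exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .fba import FluxDistribution, build_fba_problem, lexicographic_solve
from .model import MetabolicModel
from .solver import MAX, MIN, OPTIMAL, LinearProblem, SolveConfig
from .turnover import (FluxSumRecord, attach_turnover_split, flux_sum_of,
                       flux_sum_extrema)

ATTENUATION = "attenuation"
INTENSIFICATION = "intensification"
MAXIMIZE = "maximize"
MINIMIZE = "minimize"

DEFAULT_K_GRID = tuple(round(0.1 * i, 1) for i in range(11))

#: classification thresholds: a point must beat the wild-type worst case by
#: more than rel * |wt| (with an absolute floor, mmol/gDCW-hr) to count
IMPROVEMENT_REL = 1e-3
IMPROVEMENT_ABS = 1e-6

#: turnover ranges narrower than this are vacuous and skipped
DEGENERATE_RANGE_TOL = 1e-6


class DegenerateRangeError(ValueError):
    """The requested direction has no room between Phi_WT and the extremum."""


@dataclass
class ReferenceState:
    wt_growth: float
    wt_production: float
    phi_wt: Dict[str, float]
    distribution: FluxDistribution
    status: str = OPTIMAL


@dataclass
class PerturbationPoint:
    """One (metabolite, direction, k) evaluation."""

    metabolite_id: str
    direction: str
    k: float
    growth: Optional[float]
    production: Optional[float]
    growth_status: str
    production_status: str


@dataclass
class TargetReport:
    """Scan result: every evaluated point plus the classified target list."""

    target_exchange_id: str
    goal: str
    wt_growth: float
    wt_production: float
    records: Dict[str, FluxSumRecord]
    points: List[PerturbationPoint]
    #: (metabolite, direction) pairs not scanned, with reason codes
    skipped: Dict[Tuple[str, str], str]
    #: (metabolite_id, direction, best_k, best_production, growth_at_best)
    targets: List[Tuple[str, str, float, float, float]]
    metadata: Dict[str, object] = field(default_factory=dict)

    def production_profile(self, metabolite_id: str, direction: str
                           ) -> List[Tuple[float, Optional[float], Optional[float]]]:
        series = [(p.k, p.growth, p.production) for p in self.points
                  if p.metabolite_id == metabolite_id and p.direction == direction]
        if not series:
            raise KeyError(
                f"({metabolite_id}, {direction}) was not scanned"
                + (f": {self.skipped[(metabolite_id, direction)]}"
                   if (metabolite_id, direction) in self.skipped else ""))
        return sorted(series, key=lambda t: t[0])

    # -- serialization -----------------------------------------------------
    def points_table(self) -> str:
        """TSV of every perturbation point."""
        lines = ["metabolite\tdirection\tk\tgrowth\tproduction\t"
                 "growth_status\tproduction_status"]
        for p in self.points:
            lines.append("\t".join([
                p.metabolite_id, p.direction, repr(p.k),
                "" if p.growth is None else repr(p.growth),
                "" if p.production is None else repr(p.production),
                p.growth_status, p.production_status]))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "objective": {"target_exchange_id": self.target_exchange_id,
                          "goal": self.goal},
            "wt_growth": self.wt_growth,
            "wt_production": self.wt_production,
            "flux_sum_records": {
                m: {"phi_wt": r.phi_wt, "phi_min": r.phi_min,
                    "phi_max": None if math.isinf(r.phi_max) else r.phi_max}
                for m, r in self.records.items()},
            "targets": [
                {"metabolite_id": m, "direction": d, "best_k": k,
                 "best_production": prod, "growth_at_best": growth}
                for (m, d, k, prod, growth) in self.targets],
            "skipped": {f"{m}|{d}": reason
                        for (m, d), reason in sorted(self.skipped.items())},
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def adverse_sense(goal: str) -> str:
    """Worst-case sense for the target exchange: the opposite of the goal."""
    if goal == MAXIMIZE:
        return MIN
    if goal == MINIMIZE:
        return MAX
    raise ValueError(f"goal must be '{MAXIMIZE}' or '{MINIMIZE}', got {goal!r}")


def reference_state(model: MetabolicModel, target_exchange_id: str,
                    goal: str = MAXIMIZE,
                    config: Optional[SolveConfig] = None,
                    exclude: Iterable[str] = ()) -> ReferenceState:
    """Wild-type growth, worst-case production, and per-metabolite Phi_WT.

    The wild-type vertex is pinned lexicographically (biomass max, then the
    goal-adverse target optimum), so Phi_WT is well defined under alternate
    FBA optima; the convention is recorded in scan metadata.
    """
    config = config or SolveConfig()
    model.reaction(target_exchange_id)
    dist = lexicographic_solve(
        model, (model.biomass_reaction_id, MAX),
        (target_exchange_id, adverse_sense(goal)), config)
    if dist.status != OPTIMAL:
        return ReferenceState(wt_growth=math.nan, wt_production=math.nan,
                              phi_wt={}, distribution=dist, status=dist.status)
    excluded = set(exclude)
    phi_wt = {}
    for met in model.internal_metabolites:
        if met.id in excluded or not model.incident_reactions(met.id):
            continue
        phi_wt[met.id] = flux_sum_of(dist, model, met.id)
    return ReferenceState(wt_growth=dist.primary_value,
                          wt_production=dist.objective_value,
                          phi_wt=phi_wt, distribution=dist)


def perturbation_bound(record: FluxSumRecord, direction: str, k: float
                       ) -> Tuple[float, float]:
    """The (lb, ub) imposed on Phi_i by C1 or C2 at level k."""
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"k must lie in [0, 1], got {k}")
    if direction == ATTENUATION:
        if record.phi_wt - record.phi_min <= DEGENERATE_RANGE_TOL:
            raise DegenerateRangeError(
                f"{record.metabolite_id}: phi_wt == phi_min, attenuation vacuous")
        return (-math.inf, record.phi_min + k * (record.phi_wt - record.phi_min))
    if direction == INTENSIFICATION:
        if math.isinf(record.phi_max):
            raise DegenerateRangeError(
                f"{record.metabolite_id}: phi_max unbounded, intensification "
                f"level undefined")
        if record.phi_max - record.phi_wt <= DEGENERATE_RANGE_TOL:
            raise DegenerateRangeError(
                f"{record.metabolite_id}: phi_wt == phi_max, intensification vacuous")
        return (record.phi_wt + k * (record.phi_max - record.phi_wt), math.inf)
    raise ValueError(f"unknown direction {direction!r}")


def _perturbed_problem(model: MetabolicModel, record: FluxSumRecord,
                       direction: str, k: float, config: SolveConfig
                       ) -> Tuple[LinearProblem, "FluxSplit"]:
    problem = build_fba_problem(model)
    split = attach_turnover_split(problem, model, record.metabolite_id, config)
    lb, ub = perturbation_bound(record, direction, k)
    problem.add_constraint(split.phi_coefficients(), lb=lb, ub=ub)
    return problem, split


def growth_under_perturbation(model: MetabolicModel, metabolite_id: str,
                              direction: str, k: float,
                              record: FluxSumRecord,
                              config: Optional[SolveConfig] = None
                              ) -> Tuple[Optional[float], str]:
    """Maximum biomass B_ik under the C1/C2 turnover constraint.

    Returns ``(B_ik, status)``; an infeasible MILP yields ``(None,
    "infeasible")`` rather than growth 0.  Raises
    :class:`DegenerateRangeError` when the direction has no room.
    """
    config = config or SolveConfig()
    assert record.metabolite_id == metabolite_id
    problem, split = _perturbed_problem(model, record, direction, k, config)
    problem.set_objective({model.biomass_reaction_id: 1.0}, sense=MAX)
    solution = problem.solve(config)
    if solution.status != OPTIMAL:
        return None, solution.status
    split.check_big_M(solution, config.integer_tolerance)
    return solution.objective_value, OPTIMAL


def worst_case_production(model: MetabolicModel, target_exchange_id: str,
                          goal: str, metabolite_id: str, direction: str,
                          k: float, record: FluxSumRecord, growth_floor: float,
                          config: Optional[SolveConfig] = None
                          ) -> Tuple[Optional[float], str]:
    """Guaranteed target production at level k given the growth floor B_ik.

    The target exchange is optimized in the goal-adverse sense under the same
    turnover constraint plus ``v_biomass >= B_ik`` (minus the configured
    slack, to absorb MILP tolerance mismatch between the two solves).
    """
    config = config or SolveConfig()
    problem, split = _perturbed_problem(model, record, direction, k, config)
    slack = config.stage_slack(growth_floor)
    problem.add_constraint({model.biomass_reaction_id: 1.0},
                           lb=growth_floor - slack)
    problem.set_objective({target_exchange_id: 1.0}, sense=adverse_sense(goal))
    solution = problem.solve(config)
    if solution.status != OPTIMAL:
        return None, solution.status
    split.check_big_M(solution, config.integer_tolerance)
    return solution.objective_value, OPTIMAL


def _improves(goal: str, production: float, wt_production: float) -> bool:
    threshold = max(IMPROVEMENT_ABS, IMPROVEMENT_REL * abs(wt_production))
    if goal == MAXIMIZE:
        return production - wt_production > threshold
    return wt_production - production > threshold


def scan(model: MetabolicModel, target_exchange_id: str, goal: str = MAXIMIZE,
         directions: Sequence[str] = (ATTENUATION, INTENSIFICATION),
         k_grid: Sequence[float] = DEFAULT_K_GRID,
         config: Optional[SolveConfig] = None,
         exclude: Iterable[str] = ()) -> TargetReport:
    """Full flux-sum scan over all internal metabolites.

    Deterministic given (model, config): metabolites are visited in model
    order, the k grid in ascending order, and the backend solver is
    deterministic.
    """
    config = config or SolveConfig()
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    k_grid = sorted(k_grid)
    if k_grid[0] < 0.0 or k_grid[-1] > 1.0:
        raise ValueError("k grid values must lie in [0, 1]")
    for d in directions:
        if d not in (ATTENUATION, INTENSIFICATION):
            raise ValueError(f"unknown direction {d!r}")

    ref = reference_state(model, target_exchange_id, goal, config, exclude)
    if ref.status != OPTIMAL:
        return TargetReport(
            target_exchange_id=target_exchange_id, goal=goal,
            wt_growth=math.nan, wt_production=math.nan, records={},
            points=[], skipped={("*", "*"): f"reference state {ref.status}"},
            targets=[], metadata=_scan_metadata(model, config, k_grid, exclude))

    records: Dict[str, FluxSumRecord] = {}
    points: List[PerturbationPoint] = []
    skipped: Dict[Tuple[str, str], str] = {}
    best: Dict[Tuple[str, str], Tuple[float, float, float]] = {}

    for met_id in ref.phi_wt:
        phi_min, phi_max = flux_sum_extrema(model, met_id, config)
        record = FluxSumRecord(metabolite_id=met_id, phi_wt=ref.phi_wt[met_id],
                               phi_min=phi_min, phi_max=phi_max)
        record.validate()
        records[met_id] = record
        for direction in directions:
            try:
                perturbation_bound(record, direction, 0.0)
            except DegenerateRangeError as err:
                skipped[(met_id, direction)] = str(err)
                continue
            for k in k_grid:
                growth, g_status = growth_under_perturbation(
                    model, met_id, direction, k, record, config)
                if g_status != OPTIMAL:
                    points.append(PerturbationPoint(
                        met_id, direction, k, None, None, g_status, "not_attempted"))
                    continue
                production, p_status = worst_case_production(
                    model, target_exchange_id, goal, met_id, direction, k,
                    record, growth, config)
                points.append(PerturbationPoint(
                    met_id, direction, k, growth, production, g_status, p_status))
                if p_status == OPTIMAL and _improves(goal, production,
                                                     ref.wt_production):
                    key = (met_id, direction)
                    better = key not in best or (
                        production > best[key][1] if goal == MAXIMIZE
                        else production < best[key][1])
                    if better:
                        best[key] = (k, production, growth)

    targets = [(m, d, k, prod, growth)
               for (m, d), (k, prod, growth) in sorted(best.items())]
    metadata = _scan_metadata(model, config, k_grid, exclude)
    metadata["non_growing_wild_type"] = abs(ref.wt_growth) <= 1e-9
    return TargetReport(
        target_exchange_id=target_exchange_id, goal=goal,
        wt_growth=ref.wt_growth, wt_production=ref.wt_production,
        records=records, points=points, skipped=skipped, targets=targets,
        metadata=metadata)


def _scan_metadata(model: MetabolicModel, config: SolveConfig,
                   k_grid: Sequence[float], exclude: Iterable[str]
                   ) -> Dict[str, object]:
    return {
        "phi_wt_convention": "lexicographic (biomass max, then goal-adverse "
                             "target optimum)",
        "improvement_threshold_rel": IMPROVEMENT_REL,
        "improvement_threshold_abs": IMPROVEMENT_ABS,
        "degenerate_range_tol": DEGENERATE_RANGE_TOL,
        "big_M": config.big_M,
        "integer_tolerance": config.integer_tolerance,
        "stage_slack_rel": config.slack_rel,
        "stage_slack_abs": config.slack_abs,
        "k_grid": list(k_grid),
        "excluded_metabolites": sorted(exclude),
        "biomass_reaction_id": model.biomass_reaction_id,
        "non_growing_wild_type": False,
    }


def production_profile(report: TargetReport, metabolite_id: str,
                       direction: str
                       ) -> List[Tuple[float, Optional[float], Optional[float]]]:
    """Ordered (k, growth, production) series for one scanned pair."""
    return report.production_profile(metabolite_id, direction)
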