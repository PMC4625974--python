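"""Flux balance analysis: the LP core and the lexicographic two-stage solve.

FBA maximizes a cellular objective Z = sum_j c_j v_j subject to steady-state
mass balance (sum_j S_ij v_j = 0 for every internal metabolite i) and flux
capacity bounds alpha_j <= v_j <= beta_j.

Because the FBA optimum is usually degenerate, downstream quantities that
depend on the optimal *flux vector* (not just the optimal value) are pinned
with :func:`lexicographic_solve`: the primary objective is optimized first,
re-imposed as a bound (with a tiny slack, see ``SolveConfig``), and a
secondary objective is then optimized to remove alternative-optima ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .model import MetabolicModel, UnknownReactionError
from .solver import MAX, OPTIMAL, LinearProblem, Solution, SolveConfig


@dataclass
class FluxDistribution:
    """One steady-state flux vector and the objective it optimized."""

    fluxes: Dict[str, float]
    objective_id: str
    objective_value: Optional[float]
    status: str
    #: for lexicographic solves: the primary objective's fixed value
    primary_value: Optional[float] = None

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def build_fba_problem(model: MetabolicModel) -> LinearProblem:
    """LP skeleton: one variable per reaction, one balance row per internal metabolite."""
    problem = LinearProblem()
    for rxn in model.reactions:
        problem.add_variable(rxn.id, lb=rxn.lower_bound, ub=rxn.upper_bound)
    internal = {m.id for m in model.internal_metabolites}
    balance: Dict[str, Dict[str, float]] = {m: {} for m in internal}
    for rxn in model.reactions:
        for met_id, coef in rxn.stoichiometry.items():
            if met_id in internal:
                balance[met_id][rxn.id] = balance[met_id].get(rxn.id, 0.0) + coef
    for met_id in internal:
        if balance[met_id]:
            problem.add_constraint(balance[met_id], lb=0.0, ub=0.0)
    return problem


def _distribution(model: MetabolicModel, solution: Solution,
                  objective_id: str) -> FluxDistribution:
    if solution.status != OPTIMAL:
        return FluxDistribution(fluxes={}, objective_id=objective_id,
                                objective_value=None, status=solution.status)
    fluxes = {r.id: solution[r.id] for r in model.reactions}
    return FluxDistribution(fluxes=fluxes, objective_id=objective_id,
                            objective_value=solution.objective_value,
                            status=OPTIMAL)


def solve_fba(model: MetabolicModel, objective_id: Optional[str] = None,
              sense: str = MAX,
              config: Optional[SolveConfig] = None) -> FluxDistribution:
    """Optimize a single reaction flux (default: the model's biomass reaction)."""
    config = config or SolveConfig()
    if objective_id is None:
        objective_id = model.biomass_reaction_id
    model.reaction(objective_id)  # raises UnknownReactionError
    problem = build_fba_problem(model)
    problem.set_objective({objective_id: 1.0}, sense=sense)
    return _distribution(model, problem.solve(config), objective_id)


def fix_stage_objective(problem: LinearProblem, objective_id: str,
                        optimum: float, sense: str,
                        config: SolveConfig) -> None:
    """Constrain a solved stage's objective to stay within slack of its optimum."""
    slack = config.stage_slack(optimum)
    if sense == MAX:
        problem.add_constraint({objective_id: 1.0}, lb=optimum - slack)
    else:
        problem.add_constraint({objective_id: 1.0}, ub=optimum + slack)


def lexicographic_solve(model: MetabolicModel,
                        primary: Tuple[str, str],
                        secondary: Tuple[str, str],
                        config: Optional[SolveConfig] = None) -> FluxDistribution:
    """Optimize ``primary``, hold it at its optimum, then optimize ``secondary``.

    ``primary`` and ``secondary`` are ``(reaction_id, sense)`` pairs with
    sense in {"max", "min"}.  Returns the stage-2 flux distribution; its
    ``primary_value`` records the stage-1 optimum.  A stage-1 infeasibility
    is propagated; stage 2 cannot be infeasible when the slack is
    non-negative (asserted).
    """
    config = config or SolveConfig()
    primary_id, primary_sense = primary
    secondary_id, secondary_sense = secondary
    model.reaction(primary_id)
    model.reaction(secondary_id)

    stage1 = solve_fba(model, primary_id, primary_sense, config)
    if stage1.status != OPTIMAL:
        return FluxDistribution(fluxes={}, objective_id=secondary_id,
                                objective_value=None, status=stage1.status)

    problem = build_fba_problem(model)
    fix_stage_objective(problem, primary_id, stage1.objective_value,
                        primary_sense, config)
    problem.set_objective({secondary_id: 1.0}, sense=secondary_sense)
    solution = problem.solve(config)
    assert solution.status == OPTIMAL, (
        f"stage-2 re-solve unexpectedly {solution.status} "
        f"(primary {primary_id} fixed at {stage1.objective_value})")
    dist = _distribution(model, solution, secondary_id)
    dist.primary_value = stage1.objective_value
    return dist
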