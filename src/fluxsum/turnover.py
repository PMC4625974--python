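"""Metabolite turnover ("flux-sum") quantification and its MILP linearization.

At steady state the total generation and total consumption of an internal
metabolite are equal, so its turnover is

    Phi_i = 0.5 * sum_j |S_ij * v_j|

over the reactions j incident to i.  Evaluating Phi at a known flux vector
is a plain sum (:func:`flux_sum_of`).  Placing Phi in an objective or
constraint requires splitting each signed rate into non-negative generation
and consumption components,

    S_ij v_j = g+_ij - g-_ij,   g+_ij <= M I+_ij,  g-_ij <= M I-_ij,
    I+_ij + I-_ij = 1,          I in {0, 1},

so that Phi_i = 0.5 * sum_j (g+_ij + g-_ij) is linear.  The binary
indicators force one side of the split to zero; without them a maximization
of Phi could inflate both components.  Binaries (and their big-M caps) are
instantiated only for the reactions incident to the instrumented metabolite,
and are dropped entirely when a reaction's bounds already confine
S_ij * v_j to one sign — a presolve reduction with identical optima that can
be disabled (``SolveConfig.use_sign_presolve``) for cross-checking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .fba import FluxDistribution, build_fba_problem
from .model import (BoundaryMetaboliteError, DegenerateMetaboliteError,
                    MetabolicModel)
from .solver import (MAX, MIN, OPTIMAL, UNBOUNDED, BigMError,
                     LinearProblem, Solution, SolveConfig)


@dataclass
class FluxSumRecord:
    """Reference turnover triple for one metabolite: feasible range and wild type."""

    metabolite_id: str
    phi_wt: float
    phi_min: float
    phi_max: float  # math.inf when the maximization is unbounded

    def validate(self, tol: float = 1e-6) -> None:
        if not (-tol <= self.phi_min <= self.phi_wt + tol):
            raise ValueError(
                f"{self.metabolite_id}: phi_min {self.phi_min} > phi_wt {self.phi_wt}")
        if self.phi_wt > self.phi_max + tol:
            raise ValueError(
                f"{self.metabolite_id}: phi_wt {self.phi_wt} > phi_max {self.phi_max}")


@dataclass
class FluxSplit:
    """Handles to the generation/consumption split of one metabolite.

    Maps incident reaction id -> auxiliary variable name.  ``binaries`` lists
    the reactions that actually carry indicator variables (the sign-forced
    ones do not, unless presolve is disabled).
    """

    metabolite_id: str
    gpos: Dict[str, str]
    gneg: Dict[str, str]
    ipos: Dict[str, str]
    ineg: Dict[str, str]
    big_M: float

    def phi_coefficients(self) -> Dict[str, float]:
        """Coefficients expressing Phi_i = 0.5 * sum (g+ + g-)."""
        coeffs = {name: 0.5 for name in self.gpos.values()}
        coeffs.update({name: 0.5 for name in self.gneg.values()})
        return coeffs

    def check_big_M(self, solution: Solution, tol: float = 1e-6) -> None:
        """Raise if any split variable sits at its M cap (M too small)."""
        for rxn_id in self.ipos:  # only binary-capped variables can saturate M
            for name in (self.gpos[rxn_id], self.gneg[rxn_id]):
                if solution.values.get(name, 0.0) >= self.big_M - tol * max(1.0, self.big_M):
                    raise BigMError(
                        f"split variable {name} reached big-M cap {self.big_M}; "
                        f"increase SolveConfig.big_M")


def effective_big_M(model: MetabolicModel, config: SolveConfig) -> float:
    """Validate big_M against the model's finite bounds; auto-raise if too small."""
    cap = model.max_finite_bound()
    if config.big_M > cap:
        return config.big_M
    raised = 10.0 * cap
    warnings.warn(
        f"big_M={config.big_M} does not exceed the largest finite flux bound "
        f"({cap}); raising to {raised}", stacklevel=2)
    return raised


def flux_sum_of(distribution: FluxDistribution, model: MetabolicModel,
                metabolite_id: str) -> float:
    """Evaluate Phi_i = 0.5 * sum_j |S_ij v_j| at a solved flux distribution."""
    met = model.metabolite(metabolite_id)
    if met.is_boundary:
        raise BoundaryMetaboliteError(
            f"flux-sum is undefined for boundary metabolite '{metabolite_id}'")
    if distribution.status != OPTIMAL:
        raise ValueError("flux_sum_of requires an optimal flux distribution")
    total = 0.0
    for rxn in model.incident_reactions(metabolite_id):
        total += abs(rxn.stoichiometry[metabolite_id] * distribution.fluxes[rxn.id])
    return 0.5 * total


def attach_turnover_split(problem: LinearProblem, model: MetabolicModel,
                          metabolite_id: str,
                          config: Optional[SolveConfig] = None) -> FluxSplit:
    """Add the g+/g-/indicator machinery for one metabolite to an FBA problem.

    ``problem`` must already carry the v_j variables and steady-state rows
    (see :func:`fluxsum.fba.build_fba_problem`).  Returns handles so callers
    can put Phi_i into objectives or constraints.  Attaching the machinery
    never changes the optimum of an objective that ignores Phi_i.
    """
    config = config or SolveConfig()
    met = model.metabolite(metabolite_id)
    if met.is_boundary:
        raise BoundaryMetaboliteError(
            f"cannot instrument boundary metabolite '{metabolite_id}'")
    incident = model.incident_reactions(metabolite_id)
    if not incident:
        raise DegenerateMetaboliteError(
            f"metabolite '{metabolite_id}' has no incident reactions")

    big_m = effective_big_M(model, config)
    split = FluxSplit(metabolite_id=metabolite_id, gpos={}, gneg={},
                      ipos={}, ineg={}, big_M=big_m)
    for rxn in incident:
        s = rxn.stoichiometry[metabolite_id]
        # range of the signed rate y = S_ij * v_j over the flux bounds
        y_lo = min(s * rxn.lower_bound, s * rxn.upper_bound)
        y_hi = max(s * rxn.lower_bound, s * rxn.upper_bound)
        gp = f"g+[{metabolite_id}|{rxn.id}]"
        gn = f"g-[{metabolite_id}|{rxn.id}]"
        sign_forced = config.use_sign_presolve and (y_lo >= 0.0 or y_hi <= 0.0)
        if sign_forced:
            # the split is already unambiguous; no indicators needed
            problem.add_variable(gp, lb=0.0, ub=math.inf if y_hi > 0 else 0.0)
            problem.add_variable(gn, lb=0.0, ub=math.inf if y_lo < 0 else 0.0)
        else:
            ip = f"I+[{metabolite_id}|{rxn.id}]"
            ineg = f"I-[{metabolite_id}|{rxn.id}]"
            problem.add_variable(gp, lb=0.0, ub=big_m)
            problem.add_variable(gn, lb=0.0, ub=big_m)
            problem.add_variable(ip, lb=0.0, ub=1.0, integer=True)
            problem.add_variable(ineg, lb=0.0, ub=1.0, integer=True)
            problem.add_constraint({gp: 1.0, ip: -big_m}, ub=0.0)
            problem.add_constraint({gn: 1.0, ineg: -big_m}, ub=0.0)
            problem.add_constraint({ip: 1.0, ineg: 1.0}, lb=1.0, ub=1.0)
            split.ipos[rxn.id] = ip
            split.ineg[rxn.id] = ineg
        # S_ij v_j = g+ - g-
        problem.add_constraint({rxn.id: s, gp: -1.0, gn: 1.0}, lb=0.0, ub=0.0)
        split.gpos[rxn.id] = gp
        split.gneg[rxn.id] = gn
    return split


def flux_sum_extrema(model: MetabolicModel, metabolite_id: str,
                     config: Optional[SolveConfig] = None
                     ) -> Tuple[float, float]:
    """Feasible turnover range (Phi_min, Phi_max) of one metabolite.

    Two MILPs under mass balance and flux bounds only (no growth
    constraint).  Phi_max is ``math.inf`` when the maximization is
    unbounded.  Raises if the model itself is infeasible.
    """
    config = config or SolveConfig()
    results = []
    for sense in (MIN, MAX):
        problem = build_fba_problem(model)
        split = attach_turnover_split(problem, model, metabolite_id, config)
        problem.set_objective(split.phi_coefficients(), sense=sense)
        solution = problem.solve(config)
        if solution.status == UNBOUNDED and sense == MAX:
            results.append(math.inf)
            continue
        if solution.status != OPTIMAL:
            raise RuntimeError(
                f"flux-sum {sense}imization for '{metabolite_id}' "
                f"terminated {solution.status}")
        if sense == MAX:
            try:
                split.check_big_M(solution, config.integer_tolerance)
            except BigMError:
                # a split variable saturated its cap while *maximizing*
                # turnover: the true maximum exceeds any finite M
                results.append(math.inf)
                continue
        else:
            split.check_big_M(solution, config.integer_tolerance)
        results.append(max(0.0, solution.objective_value))
    phi_min, phi_max = results
    return phi_min, phi_max
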