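"""Binary-free LP oracle for all-irreversible networks.

On a network whose fluxes are confined to v >= 0, the turnover of metabolite
i is the *linear* expression 0.5 * sum_j |S_ij| v_j, so every quantity the
MILP workflow computes (turnover extrema, perturbed growth, worst-case
production) is a plain LP.  This module solves those LPs directly with
``scipy.optimize.linprog``, building its own dense matrices from the model —
deliberately sharing no code with the package's solver layer — so it can
serve as an independent cross-check of the big-M integer formulation.
"""

import math

import numpy as np
from scipy.optimize import linprog

# stage-optimum slack, matching the convention of the implementation under
# test: without the same rule, the slack leaks into worst-case production at
# sensitivity ~1 and shows up as a spurious deviation
SLACK = 1e-9


def _matrices(model):
    rxn_ids = [r.id for r in model.reactions]
    col = {rid: j for j, rid in enumerate(rxn_ids)}
    internal = [m.id for m in model.internal_metabolites]
    row = {mid: i for i, mid in enumerate(internal)}
    S = np.zeros((len(internal), len(rxn_ids)))
    for r in model.reactions:
        for mid, coef in r.stoichiometry.items():
            if mid in row:
                S[row[mid], col[r.id]] += coef
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    assert (lb >= 0).all(), "oracle is valid only for all-irreversible networks"
    return S, lb, ub, col, row


def phi_row(model, metabolite_id):
    """Coefficients of Phi_i = 0.5 * sum |S_ij| v_j over reaction columns."""
    _, _, _, col, _ = _matrices(model)
    row = np.zeros(len(col))
    for r in model.reactions:
        if metabolite_id in r.stoichiometry:
            row[col[r.id]] += 0.5 * abs(r.stoichiometry[metabolite_id])
    return row


def solve(model, objective, sense, extra_rows=()):
    """LP over the flux polytope.

    objective: dense coefficient vector; extra_rows: (row, lo, hi) triples.
    Returns (status, objective_value, flux_vector).
    """
    S, lb, ub, col, _ = _matrices(model)
    sign = -1.0 if sense == "max" else 1.0
    a_ub, b_ub = [], []
    for row, lo, hi in extra_rows:
        if math.isfinite(hi):
            a_ub.append(row)
            b_ub.append(hi)
        if math.isfinite(lo):
            a_ub.append(-row)
            b_ub.append(-lo)
    res = linprog(sign * objective, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  A_ub=np.array(a_ub) if a_ub else None,
                  b_ub=np.array(b_ub) if b_ub else None,
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    assert res.status == 0, res.message
    return "optimal", float(sign * res.fun), res.x


def unit_objective(model, rxn_id):
    _, _, _, col, _ = _matrices(model)
    v = np.zeros(len(col))
    v[col[rxn_id]] = 1.0
    return v


def lexicographic(model, primary, secondary):
    """(primary_opt, secondary_opt, flux_vector) via two chained LPs."""
    p_id, p_sense = primary
    s_id, s_sense = secondary
    status, p_opt, _ = solve(model, unit_objective(model, p_id), p_sense)
    assert status == "optimal"
    slack = max(SLACK, SLACK * abs(p_opt))
    row = unit_objective(model, p_id)
    bound = (p_opt - slack, math.inf) if p_sense == "max" else (-math.inf, p_opt + slack)
    status, s_opt, x = solve(model, unit_objective(model, s_id), s_sense,
                             extra_rows=[(row, *bound)])
    assert status == "optimal"
    return p_opt, s_opt, x


def flux_sum_at(model, metabolite_id, fluxes_by_id):
    """Phi_i evaluated at a flux dict by direct summation."""
    total = 0.0
    for r in model.reactions:
        if metabolite_id in r.stoichiometry:
            total += abs(r.stoichiometry[metabolite_id] * fluxes_by_id[r.id])
    return 0.5 * total


def phi_extrema(model, metabolite_id):
    row = phi_row(model, metabolite_id)
    _, lo, _ = solve(model, row, "min")
    status, hi, _ = solve(model, row, "max")
    return lo, (math.inf if status == "unbounded" else hi)


def perturbed_growth(model, metabolite_id, direction, k, record):
    """B_ik under the C1/C2 turnover constraint, as a pure LP."""
    row = phi_row(model, metabolite_id)
    if direction == "attenuation":
        bound = (-math.inf, record.phi_min + k * (record.phi_wt - record.phi_min))
    else:
        bound = (record.phi_wt + k * (record.phi_max - record.phi_wt), math.inf)
    status, growth, _ = solve(model, unit_objective(model, model.biomass_reaction_id),
                              "max", extra_rows=[(row, *bound)])
    return status, growth, bound


def worst_case(model, target_id, goal, metabolite_id, direction, k, record,
               growth_floor):
    status, own_growth, bound = perturbed_growth(model, metabolite_id,
                                                 direction, k, record)
    assert status == "optimal"
    # The caller's floor comes from the MILP route, which may exceed this
    # LP's optimum by solver tolerance; clip so the oracle LP stays feasible.
    # The two floors agree to the growth-comparison tolerance, asserted by
    # the caller.
    floor = min(growth_floor, own_growth)
    row = phi_row(model, metabolite_id)
    biomass_row = unit_objective(model, model.biomass_reaction_id)
    slack = max(SLACK, SLACK * abs(floor))
    sense = "min" if goal == "maximize" else "max"
    status, production, _ = solve(
        model, unit_objective(model, target_id), sense,
        extra_rows=[(row, *bound), (biomass_row, floor - slack, math.inf)])
    assert status == "optimal"
    return production
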