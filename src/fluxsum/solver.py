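"""Narrow LP/MILP solver interface.

One builder class (:class:`LinearProblem`) accumulates variables, linear
constraints and an objective, and dispatches to ``scipy.optimize.milp``
(HiGHS).  HiGHS solves both the pure LPs and the big-M integer programs used
by the turnover machinery, runs single-threaded and is deterministic, which
is what the byte-identical-rerun contract of the CLI relies on.

Nothing outside this module touches scipy's optimize API, so an alternative
backend only needs to re-implement :meth:`LinearProblem.solve`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

MAX = "max"
MIN = "min"

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """Solver terminated abnormally (limit hit or internal failure)."""


class BigMError(RuntimeError):
    """An auxiliary variable reached its big-M cap: M was too small."""


@dataclass(frozen=True)
class SolveConfig:
    """Numerical settings shared by every solve.

    big_M is the cap on the generation/consumption split variables,
    mmol/gDCW-hr; it must exceed every finite flux bound of the model
    (validated, and auto-raised with a warning, by the turnover module).
    """

    lp_tolerance: float = 1e-9
    integer_tolerance: float = 1e-6
    big_M: float = 1000.0
    time_limit: Optional[float] = 300.0
    #: relative / absolute slack used when an optimum of a previous stage is
    #: re-imposed as a bound (lexicographic solves, growth floors)
    slack_rel: float = 1e-9
    slack_abs: float = 1e-9
    #: when True, incident reactions whose bounds confine the flux to one
    #: sign get a forced split instead of binary indicators
    use_sign_presolve: bool = True

    def stage_slack(self, value: float) -> float:
        return max(self.slack_abs, self.slack_rel * abs(value))

    def with_(self, **kwargs) -> "SolveConfig":
        return replace(self, **kwargs)


@dataclass
class Solution:
    status: str
    values: Dict[str, float]
    objective_value: Optional[float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


_STATUS_MAP = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


class LinearProblem:
    """Incrementally built LP/MILP with named variables and constraints."""

    def __init__(self) -> None:
        self._var_names: List[str] = []
        self._var_pos: Dict[str, int] = {}
        self._lb: List[float] = []
        self._ub: List[float] = []
        self._integer: List[bool] = []
        self._rows: List[Tuple[Dict[int, float], float, float]] = []
        self._objective: Dict[int, float] = {}
        self._sense: str = MAX

    # -- construction ------------------------------------------------------
    def add_variable(self, name: str, lb: float = 0.0, ub: float = math.inf,
                     integer: bool = False) -> None:
        if name in self._var_pos:
            raise ValueError(f"variable '{name}' already exists")
        self._var_pos[name] = len(self._var_names)
        self._var_names.append(name)
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(integer)

    def has_variable(self, name: str) -> bool:
        return name in self._var_pos

    def set_variable_bounds(self, name: str, lb: float, ub: float) -> None:
        pos = self._var_pos[name]
        self._lb[pos] = lb
        self._ub[pos] = ub

    def add_constraint(self, coefficients: Mapping[str, float],
                       lb: float = -math.inf, ub: float = math.inf) -> None:
        row = {self._var_pos[n]: c for n, c in coefficients.items() if c != 0.0}
        self._rows.append((row, lb, ub))

    def set_objective(self, coefficients: Mapping[str, float], sense: str = MAX) -> None:
        if sense not in (MAX, MIN):
            raise ValueError(f"sense must be '{MAX}' or '{MIN}', got {sense!r}")
        self._objective = {self._var_pos[n]: c for n, c in coefficients.items()}
        self._sense = sense

    # -- solving -----------------------------------------------------------
    def solve(self, config: Optional[SolveConfig] = None) -> Solution:
        config = config or SolveConfig()
        n = len(self._var_names)
        c = np.zeros(n)
        for pos, coef in self._objective.items():
            c[pos] = coef
        sign = -1.0 if self._sense == MAX else 1.0

        constraints = []
        if self._rows:
            data, ri, ci = [], [], []
            bl = np.empty(len(self._rows))
            bu = np.empty(len(self._rows))
            for k, (row, lo, hi) in enumerate(self._rows):
                bl[k], bu[k] = lo, hi
                for pos, coef in row.items():
                    ri.append(k)
                    ci.append(pos)
                    data.append(coef)
            a = sparse.csr_matrix((data, (ri, ci)), shape=(len(self._rows), n))
            constraints = [LinearConstraint(a, bl, bu)]

        options: Dict[str, object] = {"mip_rel_gap": 0.0, "presolve": True}
        if config.time_limit is not None:
            options["time_limit"] = config.time_limit

        res = milp(
            c=sign * c,
            constraints=constraints,
            integrality=np.array(self._integer, dtype=int),
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            options=options,
        )
        status = _STATUS_MAP.get(res.status)
        if status is None:
            raise SolverError(f"solver terminated abnormally: {res.message}")
        if status != OPTIMAL:
            return Solution(status=status, values={}, objective_value=None)
        values = {name: float(res.x[self._var_pos[name]]) for name in self._var_names}
        return Solution(status=OPTIMAL, values=values,
                        objective_value=float(res.fun * sign))
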