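"""Thin MILP solver adapter.

The pathway model only needs a solver that honours variable boxes,
integrality, a relative optimality gap and a wall-clock limit, and that
returns the incumbent when the limit triggers.  The default backend drives
HiGHS through :func:`scipy.optimize.milp`; any object implementing
:class:`MilpBackend` can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["MilpProblem", "MilpResult", "MilpBackend", "HighsBackend"]


@dataclass
class MilpProblem:
    """min c·x  s.t.  A_ub x ≤ b_ub,  A_eq x = b_eq,  lb ≤ x ≤ ub."""

    c: np.ndarray
    A_ub: np.ndarray | None
    b_ub: np.ndarray | None
    A_eq: np.ndarray | None
    b_eq: np.ndarray | None
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray  # 0 continuous, 1 integer


@dataclass
class MilpResult:
    x: np.ndarray | None
    objective: float | None
    status: str  # optimal | feasible_time_limit | infeasible | no_incumbent
    mip_gap: float | None = None


class MilpBackend(Protocol):
    def solve(
        self, problem: MilpProblem, *, time_limit_s: float, mip_gap: float, seed: int
    ) -> MilpResult: ...


class HighsBackend:
    """Default backend: HiGHS branch-and-bound via scipy.

    HiGHS is deterministic for a fixed model, so *seed* is accepted for
    interface compatibility but has no effect on the solve.
    """

    def solve(
        self,
        problem: MilpProblem,
        *,
        time_limit_s: float = 200.0,
        mip_gap: float = 0.0,
        seed: int = 0,
    ) -> MilpResult:
        constraints = []
        if problem.A_ub is not None and len(problem.b_ub):
            constraints.append(
                LinearConstraint(problem.A_ub, -np.inf, problem.b_ub)
            )
        if problem.A_eq is not None and len(problem.b_eq):
            constraints.append(
                LinearConstraint(problem.A_eq, problem.b_eq, problem.b_eq)
            )
        res = milp(
            c=problem.c,
            constraints=constraints,
            integrality=problem.integrality,
            bounds=Bounds(problem.lb, problem.ub),
            options={"time_limit": float(time_limit_s), "mip_rel_gap": float(mip_gap)},
        )
        gap = getattr(res, "mip_gap", None)
        if res.status == 0:
            return MilpResult(x=res.x, objective=res.fun, status="optimal", mip_gap=gap)
        if res.status == 1:  # iteration/time limit
            if res.x is not None:
                return MilpResult(
                    x=res.x, objective=res.fun, status="feasible_time_limit", mip_gap=gap
                )
            return MilpResult(x=None, objective=None, status="no_incumbent")
        if res.status == 2:
            return MilpResult(x=None, objective=None, status="infeasible")
        return MilpResult(x=None, objective=None, status="no_incumbent")
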