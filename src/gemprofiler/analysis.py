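"""Flux balance analysis (FBA) and flux variability analysis (FVA).

FBA maximises the objective Z = c'v subject to steady-state mass balance
S v = 0 and flux bounds v_l <= v <= v_u.  FVA then reports, per reaction,
the attainable [min, max] flux while retaining at least a fraction gamma of
the optimal objective (c'v >= gamma * Z0).

The linear programs are assembled on the sparse stoichiometric matrix and
solved with the HiGHS simplex/IPM via scipy — deterministic across repeated
calls and never densifying S.  Sign convention: a negative exchange flux is
uptake, positive is secretion.

Degenerate optima: Z and FVA intervals are reproducible outputs; the
particular FBA flux vector generally is not unique and is labelled so.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import GEM, GEMError, find_biomass_reaction

__all__ = ["FBAResult", "FVAResult", "SolverError", "fba", "fva"]

FEASIBILITY_TOL = 1e-9
REPORT_TOL = 1e-6


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasible/unbounded."""


@dataclass(frozen=True)
class FBAResult:
    """Outcome of one FBA solve.

    ``fluxes`` is one optimal vertex; it is generally non-unique under
    degenerate optima — only ``objective_value`` (and FVA intervals) should
    be treated as reproducible quantities.
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Mapping[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FVAResult:
    """Per-reaction flux ranges at objective fraction ``gamma``."""

    gamma: float
    z0: float
    intervals: Mapping[str, tuple[float, float]]


def _lp_arrays(gem: GEM):
    S = gem.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in gem.reactions]
    return S, bounds


def _objective_vector(gem: GEM) -> np.ndarray:
    c = gem.objective_vector()
    if not np.any(c):
        # fall back to a biomass-named reaction
        biomass = find_biomass_reaction(gem)
        c = np.zeros(len(gem.reactions))
        c[gem.reaction_ids.index(biomass)] = 1.0
    return c


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(c_min, S, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c_min,
        A_eq=S,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failed: {res.message} (status {res.status})")
    return status, res


def fba(gem: GEM) -> FBAResult:
    """Maximise the model objective at steady state.

    Raises :class:`~gemprofiler.model.AmbiguityError` when no objective is
    set and no biomass reaction can be identified.
    """
    c = _objective_vector(gem)
    S, bounds = _lp_arrays(gem)
    b_eq = np.zeros(S.shape[0])
    status, res = _solve(-c, S, b_eq, bounds)
    if status != "optimal":
        return FBAResult(status=status, objective_value=float("nan"), fluxes={})
    v = res.x
    residual = np.abs(S @ v).max() if S.shape[0] else 0.0
    if residual > REPORT_TOL:
        raise SolverError(f"mass-balance residual {residual:.2e} exceeds tolerance")
    return FBAResult(
        status="optimal",
        objective_value=float(c @ v),
        fluxes=dict(zip(gem.reaction_ids, (float(x) for x in v))),
    )


def fva(
    gem: GEM,
    reaction_ids: Optional[Sequence[str]] = None,
    gamma: float = 1.0,
) -> FVAResult:
    """Min/max flux per queried reaction at objective fraction ``gamma``.

    ``gamma=1`` keeps the network at its optimal state; ``gamma=0`` drops
    the objective constraint entirely.  Default query: all exchange
    reactions.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    base = fba(gem)
    if not base.optimal:
        raise GEMError(f"FVA base problem is {base.status}")
    z0 = base.objective_value
    if reaction_ids is None:
        reaction_ids = [r.id for r in gem.reactions if r.is_exchange]
    index = {rid: i for i, rid in enumerate(gem.reaction_ids)}
    missing = [rid for rid in reaction_ids if rid not in index]
    if missing:
        raise KeyError(f"unknown reactions for FVA: {missing}")

    c_obj = _objective_vector(gem)
    S, bounds = _lp_arrays(gem)
    b_eq = np.zeros(S.shape[0])
    # keep c'v >= gamma * z0; tiny relaxation guards against the optimum
    # itself being cut off by floating-point round-off at gamma = 1
    rhs = gamma * z0 - FEASIBILITY_TOL * max(1.0, abs(z0))
    A_ub = sparse.csr_matrix(-c_obj.reshape(1, -1))
    b_ub = np.array([-rhs])

    intervals: dict[str, tuple[float, float]] = {}
    e = np.zeros(len(gem.reactions))
    for rid in reaction_ids:
        j = index[rid]
        e[j] = 1.0
        status_lo, res_lo = _solve(e, S, b_eq, bounds, A_ub, b_ub)
        status_hi, res_hi = _solve(-e, S, b_eq, bounds, A_ub, b_ub)
        e[j] = 0.0
        if status_lo != "optimal" or status_hi != "optimal":
            raise SolverError(
                f"FVA subproblem for {rid} ended {status_lo}/{status_hi}"
            )
        lo, hi = float(res_lo.x[j]), float(res_hi.x[j])
        if lo > hi:  # numerically touching interval
            lo = hi = 0.5 * (lo + hi)
        intervals[rid] = (lo, hi)
    return FVAResult(gamma=gamma, z0=z0, intervals=intervals)
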