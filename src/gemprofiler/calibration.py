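"""Calibrate the scale factor alpha against observed growth rates.

Activity scores are in expression units and flux bounds in mM/48 h, so a
single factor alpha bridges the two (v_i = alpha * RAS_i).  The calibration
scans alpha over a log grid (default 25 points across 1e-6..1), computes
the maximal biomass flux of every condition model at each alpha, and keeps
the alpha whose per-condition predictions best match the observed growth
observable (reciprocal doubling time, 1/h).

Because predicted flux and observed growth rate live in different units,
the default score first least-squares-scales predictions onto observations
and then takes the RMSE ("scaled_rmse": shape matching); plain Pearson
correlation is also available.  Conditions without an observation (no
growth, doubling time undefined) are excluded from the score but still
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .integration import VARIANTS, IntegrationConfig, build_condition_model
from .analysis import fba
from .model import GEM
from .mur import MURProfile
from .ras import RASProfile

__all__ = [
    "GrowthObservation",
    "CalibrationTable",
    "log_grid",
    "scan_alpha",
    "match_score",
    "select_alpha",
    "calibrate",
]


@dataclass(frozen=True)
class GrowthObservation:
    """Observed growth of one condition: reciprocal doubling time in 1/h.

    ``None`` means growth was non-positive and no doubling time exists.
    """

    condition: str
    reciprocal_doubling_time: Optional[float] = None

    def __post_init__(self) -> None:
        v = self.reciprocal_doubling_time
        if v is not None and v < 0:
            raise ValueError(f"{self.condition}: reciprocal doubling time < 0")


@dataclass
class CalibrationTable:
    """Biomass flux per (alpha, condition), plus scores once selected.

    ``biomass`` is indexed by alpha (rows) and condition (columns);
    ``infeasible`` flags (alpha, condition) solves that did not reach an
    optimum (their biomass is recorded as 0).
    """

    alphas: tuple[float, ...]
    conditions: tuple[str, ...]
    biomass: pd.DataFrame
    infeasible: pd.DataFrame
    variant: str = "ras_mur"
    scores: Optional[pd.Series] = None
    metric: Optional[str] = None
    selected_alpha: Optional[float] = None

    def predictions_at(self, alpha: float) -> dict[str, float]:
        return {c: float(self.biomass.loc[alpha, c]) for c in self.conditions}


def log_grid(lo: float = 1e-6, hi: float = 1.0, n: int = 25) -> tuple[float, ...]:
    """Log-uniform alpha grid spanning [lo, hi]."""
    if not (0 < lo < hi) or n < 2:
        raise ValueError("need 0 < lo < hi and n >= 2")
    return tuple(np.logspace(math.log10(lo), math.log10(hi), n))


def scan_alpha(
    gem: GEM,
    condition_profiles: Sequence[tuple[Optional[RASProfile], Optional[MURProfile]]],
    grid: Sequence[float] = (),
    variant: str = "ras_mur",
) -> CalibrationTable:
    """FBA biomass optimum for every (alpha, condition) on the grid."""
    grid = tuple(grid) or log_grid()
    if any(a <= 0 for a in grid) or any(
        b <= a for a, b in zip(grid, grid[1:])
    ):
        raise ValueError("alpha grid must be positive and strictly increasing")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    conditions = []
    for ras_p, mur_p in condition_profiles:
        name = (ras_p.condition if ras_p is not None else None) or (
            mur_p.condition if mur_p is not None else None
        )
        if not name:
            raise ValueError("every condition needs a named RAS or MUR profile")
        conditions.append(name)
    if len(set(conditions)) != len(conditions):
        raise ValueError(f"duplicate condition names: {conditions}")

    biomass = pd.DataFrame(0.0, index=list(grid), columns=conditions)
    infeasible = pd.DataFrame(False, index=list(grid), columns=conditions)
    for alpha in grid:
        cfg = IntegrationConfig(alpha=alpha, variant=variant)
        for name, (ras_p, mur_p) in zip(conditions, condition_profiles):
            model = build_condition_model(
                gem,
                ras=ras_p if variant in ("ras", "ras_mur") else None,
                mur=mur_p if variant in ("mur", "ras_mur") else None,
                cfg=cfg,
            )
            result = fba(model)
            if result.optimal:
                biomass.loc[alpha, name] = result.objective_value
            else:
                infeasible.loc[alpha, name] = True
    return CalibrationTable(
        alphas=grid,
        conditions=tuple(conditions),
        biomass=biomass,
        infeasible=infeasible,
        variant=variant,
    )


def match_score(
    predicted: Mapping[str, float],
    observed: Sequence[GrowthObservation],
    metric: str = "scaled_rmse",
) -> float:
    """Agreement between predicted biomass fluxes and observed growth rates.

    ``scaled_rmse``: RMSE after the least-squares scaling s* = <p,o>/<p,p>
    of predictions p onto observations o (scale-free; lower is better).
    ``pearson``: correlation across conditions (higher is better; undefined
    for constant predictions or observations).
    """
    obs = {
        o.condition: float(o.reciprocal_doubling_time)
        for o in observed
        if o.reciprocal_doubling_time is not None
    }
    common = [c for c in predicted if c in obs]
    if len(common) < 2:
        raise ValueError(
            f"need >=2 observed conditions to score a match, have {len(common)}"
        )
    p = np.array([predicted[c] for c in common], dtype=float)
    o = np.array([obs[c] for c in common], dtype=float)
    if metric == "scaled_rmse":
        pp = float(p @ p)
        s = float(p @ o) / pp if pp > 0 else 0.0
        return float(np.sqrt(np.mean((s * p - o) ** 2)))
    if metric == "pearson":
        if np.ptp(p) == 0 or np.ptp(o) == 0:
            raise ValueError("pearson undefined for constant predictions/observations")
        return float(np.corrcoef(p, o)[0, 1])
    raise ValueError(f"unknown metric {metric!r}")


def select_alpha(
    table: CalibrationTable,
    observed: Sequence[GrowthObservation],
    metric: str = "scaled_rmse",
) -> float:
    """The grid alpha whose predictions best match the observations.

    Ties (including score plateaus) break toward the smaller alpha — the
    tighter model.  Alphas whose score is undefined (e.g. constant
    predictions under pearson) are skipped.  The table is annotated in
    place with scores and the selection.
    """
    if bool(table.infeasible.all(axis=None)):
        raise ValueError("all (alpha, condition) solves were infeasible")
    better = (lambda a, b: a < b) if metric == "scaled_rmse" else (lambda a, b: a > b)
    scores = pd.Series(np.nan, index=list(table.alphas))
    best_alpha = None
    best_score = None
    for alpha in table.alphas:  # ascending: strict improvement keeps smaller alpha
        try:
            score = match_score(table.predictions_at(alpha), observed, metric)
        except ValueError:
            continue
        scores[alpha] = score
        if best_score is None or better(score, best_score):
            best_alpha, best_score = alpha, score
    if best_alpha is None:
        raise ValueError("no alpha produced a defined match score")
    table.scores = scores
    table.metric = metric
    table.selected_alpha = float(best_alpha)
    return float(best_alpha)


def calibrate(
    gem: GEM,
    condition_profiles: Sequence[tuple[Optional[RASProfile], Optional[MURProfile]]],
    observed: Sequence[GrowthObservation],
    grid: Sequence[float] = (),
    variant: str = "ras_mur",
    metric: str = "scaled_rmse",
) -> CalibrationTable:
    """Scan + select in one call; returns the annotated table."""
    table = scan_alpha(gem, condition_profiles, grid, variant)
    select_alpha(table, observed, metric)
    return table
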