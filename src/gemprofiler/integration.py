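"""Condition-specific model variants: GEM-RAS, GEM-MUR, GEM-RAS-MUR.

Expression scores rescale the bounds of GPR-bearing reactions: a reaction
with score RAS_i gets its flux capped at v_i = alpha * RAS_i in every
direction that was originally open (a bound of 0 — the impossible direction
of an irreversible reaction — stays 0).  Nutrient availability caps uptake:
an exchange reaction with rate MUR_j gets lower bound -MUR_j; its secretion
(upper) bound is never touched.  Both rewrites only ever tighten bounds, so
the condition model's feasible region is a subset of the original one —
which also makes the biomass optimum non-decreasing in alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import GEM, Reaction
from .mur import MURProfile
from .ras import RASProfile

__all__ = [
    "IntegrationConfig",
    "VARIANTS",
    "apply_ras_bounds",
    "apply_mur_bounds",
    "build_condition_model",
]

VARIANTS = ("ras", "mur", "ras_mur")


@dataclass(frozen=True)
class IntegrationConfig:
    """How to build a condition model.

    alpha: the single scale factor translating activity scores into flux
    units; ras_zero_policy: whether a score of exactly 0 closes the reaction
    (``block``, the literal v_i = alpha * RAS_i reading) or leaves it alone
    (``leave``); unmapped_exchange_policy: what happens to exchange
    reactions without a MUR (``leave`` keeps model defaults — serum
    components are never quantified; ``close`` forbids their uptake).
    """

    alpha: float = 1.0
    variant: str = "ras_mur"
    ras_zero_policy: str = "block"
    unmapped_exchange_policy: str = "leave"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.ras_zero_policy not in {"block", "leave"}:
            raise ValueError(f"bad ras_zero_policy {self.ras_zero_policy!r}")
        if self.unmapped_exchange_policy not in {"leave", "close"}:
            raise ValueError(
                f"bad unmapped_exchange_policy {self.unmapped_exchange_policy!r}"
            )


def _capped(reaction: Reaction, cap: float) -> Reaction:
    lb, ub = reaction.lower_bound, reaction.upper_bound
    new_lb = -cap if lb < 0 else lb
    new_ub = cap if ub > 0 else ub
    # a forced positive lower bound can exceed a small cap; tightening wins
    if new_lb > new_ub:
        new_lb = new_ub
    return reaction.with_bounds(new_lb, new_ub)


def apply_ras_bounds(
    gem: GEM,
    ras: RASProfile,
    alpha: float,
    ras_zero_policy: str = "block",
) -> GEM:
    """Cap each scored reaction's flux at alpha * RAS in the open directions.

    Original bounds of 0 stay 0 (the impossible direction of an irreversible
    reaction).  Reactions without a score are untouched.  Returns a new
    model; the input is never modified.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    unknown = set(ras.scores) - set(gem.reaction_ids)
    if unknown:
        raise ValueError(
            f"RAS profile references reactions absent from the model: "
            f"{sorted(unknown)}"
        )
    new_reactions = []
    for r in gem.reactions:
        score = ras.scores.get(r.id)
        if score is None or (score == 0 and ras_zero_policy == "leave"):
            new_reactions.append(r)
        else:
            new_reactions.append(_capped(r, alpha * score))
    return gem.with_reactions(new_reactions)


def apply_mur_bounds(
    gem: GEM,
    mur: MURProfile,
    unmapped_exchange_policy: str = "leave",
) -> GEM:
    """Set each profiled exchange reaction's lower bound to -MUR.

    Uptake (negative flux) is thereby capped at nutrient availability; the
    secretion (upper) bound is never modified.  Unprofiled exchanges keep
    their model defaults (``leave``) or have uptake closed (``close``).
    """
    exchange_ids = {r.id for r in gem.reactions if r.is_exchange}
    not_exchange = set(mur.rates) - exchange_ids
    if not_exchange:
        raise ValueError(
            f"MUR profile entries are not exchange reactions of the model: "
            f"{sorted(not_exchange)}"
        )
    new_reactions = []
    for r in gem.reactions:
        if r.id in mur.rates:
            lb = -float(mur.rates[r.id])
            new_reactions.append(r.with_bounds(min(lb, r.upper_bound), r.upper_bound))
        elif (
            r.is_exchange
            and unmapped_exchange_policy == "close"
            and r.lower_bound < 0
        ):
            new_reactions.append(r.with_bounds(min(0.0, r.upper_bound), r.upper_bound))
        else:
            new_reactions.append(r)
    return gem.with_reactions(new_reactions)


def build_condition_model(
    gem: GEM,
    ras: Optional[RASProfile] = None,
    mur: Optional[MURProfile] = None,
    cfg: Optional[IntegrationConfig] = None,
) -> GEM:
    """Compose the RAS and/or MUR bound rewrites into one condition model.

    The two rewrites commute whenever no exchange reaction carries a GPR
    (true of Recon3D's EX_ reactions); if one does, the MUR assignment is
    applied last and wins on the exchange lower bound.
    """
    cfg = cfg or IntegrationConfig()
    needs = {"ras": (True, False), "mur": (False, True), "ras_mur": (True, True)}
    want_ras, want_mur = needs[cfg.variant]
    if want_ras != (ras is not None) or want_mur != (mur is not None):
        raise ValueError(
            f"variant {cfg.variant!r} requires ras={'yes' if want_ras else 'no'}, "
            f"mur={'yes' if want_mur else 'no'}; got ras="
            f"{'yes' if ras is not None else 'no'}, "
            f"mur={'yes' if mur is not None else 'no'}"
        )
    out = gem
    if want_ras:
        out = apply_ras_bounds(out, ras, cfg.alpha, cfg.ras_zero_policy)
    if want_mur:
        out = apply_mur_bounds(out, mur, cfg.unmapped_exchange_policy)
    return out
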