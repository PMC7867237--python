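"""Maximal Uptake Rates (MUR) from media composition / spent-medium data.

A MUR caps how fast a medium substrate can be taken up: it is the absolute
concentration change |S_F - S_I| of the substrate over the culture window
(default 48 h), in mM per window.  In availability-only mode (no spent-medium
measurement) the final concentration defaults to 0, i.e. the nutrient may be
consumed completely — this is how a plain media recipe defines uptake caps.
Fluxes are carried in mM/48 h throughout; no conversion to mmol/gDW/h is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import GEM, GEMError

__all__ = [
    "MediumMeasurement",
    "MURProfile",
    "compute_mur",
    "build_mur_profile",
    "read_media_table",
    "write_mur_profile",
    "DEFAULT_WINDOW_H",
]

DEFAULT_WINDOW_H = 48.0


@dataclass(frozen=True)
class MediumMeasurement:
    """Concentration of one substrate at the start and end of a culture window.

    ``conc_final`` defaults to 0 mM (availability-only mode: full consumption
    assumed).  Times are in hours, concentrations in mM.
    """

    metabolite: str
    exchange_reaction_id: str
    conc_initial: float
    conc_final: float = 0.0
    t_initial: float = 0.0
    t_final: float = DEFAULT_WINDOW_H

    def __post_init__(self) -> None:
        if self.conc_initial < 0 or self.conc_final < 0:
            raise ValueError(
                f"{self.metabolite}: concentrations must be non-negative"
            )
        if self.t_final <= self.t_initial:
            raise ValueError(
                f"{self.metabolite}: time window must be positive "
                f"(t_initial={self.t_initial}, t_final={self.t_final})"
            )


@dataclass(frozen=True)
class MURProfile:
    """Per-exchange-reaction maximal uptake rates for one condition (mM/window)."""

    condition: str
    rates: Mapping[str, float]
    window_h: float = DEFAULT_WINDOW_H

    def __post_init__(self) -> None:
        bad = {r: v for r, v in self.rates.items() if v < 0}
        if bad:
            raise ValueError(f"negative MUR values: {bad}")

    def __len__(self) -> int:
        return len(self.rates)


def compute_mur(
    measurement: MediumMeasurement, window_h: Optional[float] = None
) -> float:
    """|S_F - S_I| rescaled to ``window_h`` hours.

    With the default window equal to the measurement span the MUR is simply
    the absolute concentration change over that span (mM per window).
    """
    span = measurement.t_final - measurement.t_initial
    delta = abs(measurement.conc_final - measurement.conc_initial)
    if window_h is None:
        return delta
    return delta / span * float(window_h)


def build_mur_profile(
    condition: str,
    measurements: Sequence[MediumMeasurement],
    gem: GEM,
    window_h: float = DEFAULT_WINDOW_H,
) -> MURProfile:
    """One MUR per measured exchange reaction of ``gem``.

    Unmeasured exchange reactions are simply absent — their bounds are left
    untouched downstream (serum components and micronutrients are typically
    never quantified).
    """
    exchange_ids = {r.id for r in gem.reactions if r.is_exchange}
    known_ids = set(gem.reaction_ids)
    offenders = []
    for m in measurements:
        if m.exchange_reaction_id not in known_ids:
            offenders.append(f"{m.exchange_reaction_id} (not in model)")
        elif m.exchange_reaction_id not in exchange_ids:
            offenders.append(f"{m.exchange_reaction_id} (not an exchange reaction)")
    if offenders:
        raise GEMError(
            f"condition {condition!r}: measurements map to invalid exchange "
            f"reactions: {offenders}"
        )
    rates: dict[str, float] = {}
    for m in measurements:
        rates[m.exchange_reaction_id] = compute_mur(m, window_h)
    return MURProfile(condition=condition, rates=rates, window_h=window_h)


# -- I/O --------------------------------------------------------------------


def read_media_table(path) -> dict[str, list[MediumMeasurement]]:
    """Read a media/measurement table (TSV/CSV) into per-condition lists.

    Columns: condition, metabolite, exchange_id, conc_initial_mM,
    conc_final_mM (optional, default 0 = fully consumable), t_hours
    (optional, default 48).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep)
    required = {"condition", "metabolite", "exchange_id", "conc_initial_mM"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing media columns {sorted(missing)}")
    out: dict[str, list[MediumMeasurement]] = {}
    for _, row in table.iterrows():
        final = row.get("conc_final_mM", 0.0)
        final = 0.0 if pd.isna(final) else float(final)
        hours = row.get("t_hours", DEFAULT_WINDOW_H)
        hours = DEFAULT_WINDOW_H if pd.isna(hours) else float(hours)
        m = MediumMeasurement(
            metabolite=str(row["metabolite"]),
            exchange_reaction_id=str(row["exchange_id"]),
            conc_initial=float(row["conc_initial_mM"]),
            conc_final=final,
            t_initial=0.0,
            t_final=hours,
        )
        out.setdefault(str(row["condition"]), []).append(m)
    return out


def write_mur_profile(profile: MURProfile, path) -> None:
    """Export as two-column TSV (exchange_id, mur)."""
    frame = pd.DataFrame(
        {"exchange_id": list(profile.rates), "mur": list(profile.rates.values())}
    )
    frame.to_csv(path, sep="\t", index=False)
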