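"""End-to-end profiling runs: model + expression + media -> report.

One :func:`run_profile` call loads the model, derives per-condition RAS and
MUR profiles, optionally calibrates alpha against observed growth, builds
the requested model variants (expression-only, nutrients-only, combined,
and donor-expression), runs FBA per (condition, variant) and FVA on the
exchange reactions of interest, and writes the tables plus a provenance
block.  An infeasible condition degrades to a flagged row, never an abort.

All fluxes are in mM/48 h; negative exchange flux is uptake, positive is
secretion.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__ as _version
from .analysis import fva as run_fva, fba
from .calibration import (
    CalibrationTable,
    GrowthObservation,
    calibrate,
    log_grid,
)
from .integration import IntegrationConfig, build_condition_model
from .model import GEM, read_model
from .mur import MURProfile, build_mur_profile, read_media_table
from .ras import RASProfile, aggregate_expression, compute_ras_profile, read_expression_table

__all__ = [
    "ConditionInput",
    "RunConfig",
    "ProfilingReport",
    "ConfigError",
    "load_run_config",
    "run_profile",
]

logger = logging.getLogger("gemprofiler")

ALL_VARIANTS = ("ras", "mur", "ras_mur", "ras_donor_mur")

_UNITS_HEADER = (
    "# units: mM/48 h; sign convention: negative exchange flux = uptake, "
    "positive = secretion\n"
)


class ConfigError(ValueError):
    """Invalid run configuration; message names the first failing field."""


@dataclass(frozen=True)
class ConditionInput:
    expression: Optional[str] = None
    media: Optional[str] = None
    observation: Optional[float] = None  # reciprocal doubling time, 1/h


@dataclass
class RunConfig:
    model: str
    conditions: dict[str, ConditionInput]
    alpha: object = "calibrate"  # float or the string "calibrate"
    variants: tuple[str, ...] = ("ras", "mur", "ras_mur")
    fva_reactions: tuple[str, ...] = ()
    gamma: float = 1.0
    grid: tuple[float, ...] = ()
    metric: str = "scaled_rmse"
    ras_from: Optional[str] = None  # donor condition for ras_donor_mur
    normalization: str = "cpm"
    combine: str = "mean"
    missing_policy: str = "skip"
    outdir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.model).exists():
            raise ConfigError(f"model: file not found: {self.model}")
        if not self.conditions:
            raise ConfigError("conditions: at least one condition required")
        for name, ci in self.conditions.items():
            for fld in ("expression", "media"):
                p = getattr(ci, fld)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"conditions.{name}.{fld}: file not found: {p}")
        bad = set(self.variants) - set(ALL_VARIANTS)
        if bad:
            raise ConfigError(f"variants: unknown {sorted(bad)}")
        if "ras_donor_mur" in self.variants and not self.ras_from:
            raise ConfigError("ras_from: required for the ras_donor_mur variant")
        if self.ras_from and self.ras_from not in self.conditions:
            raise ConfigError(f"ras_from: unknown condition {self.ras_from!r}")
        if not (isinstance(self.alpha, (int, float)) and self.alpha > 0) and (
            self.alpha != "calibrate"
        ):
            raise ConfigError("alpha: must be a positive number or 'calibrate'")
        if not 0 <= self.gamma <= 1:
            raise ConfigError("gamma: must lie in [0, 1]")


def load_run_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config: expected a mapping at top level")
    conditions = {
        str(name): ConditionInput(
            expression=entry.get("expression"),
            media=entry.get("media"),
            observation=entry.get("observation"),
        )
        for name, entry in (raw.get("conditions") or {}).items()
    }
    kwargs = {k: v for k, v in raw.items() if k != "conditions"}
    for tup in ("variants", "fva_reactions", "grid"):
        if tup in kwargs and kwargs[tup] is not None:
            kwargs[tup] = tuple(kwargs[tup])
    try:
        return RunConfig(conditions=conditions, **kwargs)
    except TypeError as exc:
        raise ConfigError(f"config: {exc}") from exc


@dataclass
class ProfilingReport:
    """All tables one profiling run produces, plus provenance."""

    biomass: pd.DataFrame  # index condition, columns variant; NaN = not computed
    status: pd.DataFrame  # parallel status strings
    fva: pd.DataFrame  # condition, reaction_id, min_flux, max_flux
    calibration: Optional[CalibrationTable]
    alpha: float
    gamma: float
    provenance: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "biomass.tsv", "w") as fh:
            fh.write(_UNITS_HEADER)
            self.biomass.to_csv(fh, sep="\t", index_label="condition")
        with open(outdir / "fva.tsv", "w") as fh:
            fh.write(_UNITS_HEADER)
            self.fva.to_csv(fh, sep="\t", index=False)
        if self.calibration is not None:
            with open(outdir / "calibration.tsv", "w") as fh:
                fh.write(_UNITS_HEADER)
                frame = self.calibration.biomass.copy()
                frame.insert(0, "alpha", frame.index)
                if self.calibration.scores is not None:
                    frame["match_score"] = self.calibration.scores
                frame.to_csv(fh, sep="\t", index=False)
        payload = {
            "alpha": self.alpha,
            "gamma": self.gamma,
            "biomass": {
                c: {
                    v: (None if pd.isna(self.biomass.loc[c, v]) else float(self.biomass.loc[c, v]))
                    for v in self.biomass.columns
                }
                for c in self.biomass.index
            },
            "status": {
                c: dict(self.status.loc[c]) for c in self.status.index
            },
            "provenance": self.provenance,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_profiles(
    gem: GEM, cfg: RunConfig
) -> tuple[dict[str, Optional[RASProfile]], dict[str, Optional[MURProfile]]]:
    media_cache: dict[str, dict] = {}
    ras_profiles: dict[str, Optional[RASProfile]] = {}
    mur_profiles: dict[str, Optional[MURProfile]] = {}
    for name, ci in cfg.conditions.items():
        if ci.expression:
            counts = read_expression_table(ci.expression)
            abundances = aggregate_expression(counts, cfg.normalization, cfg.combine)
            ras_profiles[name] = compute_ras_profile(
                gem, abundances, cfg.missing_policy, condition=name
            )
        else:
            ras_profiles[name] = None
        if ci.media:
            if ci.media not in media_cache:
                media_cache[ci.media] = read_media_table(ci.media)
            table = media_cache[ci.media]
            if name not in table:
                raise ConfigError(
                    f"conditions.{name}.media: condition absent from {ci.media}"
                )
            mur_profiles[name] = build_mur_profile(name, table[name], gem)
        else:
            mur_profiles[name] = None
    return ras_profiles, mur_profiles


def _variant_profiles(variant, name, ras_profiles, mur_profiles, donor):
    """(ras, mur, effective_variant) for one (condition, variant) cell, or None."""
    if variant == "ras":
        ras_p = ras_profiles[name]
        return (ras_p, None, "ras") if ras_p is not None else None
    if variant == "mur":
        mur_p = mur_profiles[name]
        return (None, mur_p, "mur") if mur_p is not None else None
    if variant == "ras_mur":
        ras_p, mur_p = ras_profiles[name], mur_profiles[name]
        if ras_p is None or mur_p is None:
            return None
        return (ras_p, mur_p, "ras_mur")
    if variant == "ras_donor_mur":
        ras_p, mur_p = ras_profiles.get(donor), mur_profiles[name]
        if ras_p is None or mur_p is None:
            return None
        return (ras_p, mur_p, "ras_mur")
    raise ValueError(variant)


def run_profile(cfg: RunConfig) -> ProfilingReport:
    """Run the full profiling workflow described by ``cfg``."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    gem = read_model(cfg.model)
    ras_profiles, mur_profiles = _load_profiles(gem, cfg)
    conditions = list(cfg.conditions)

    observations = [
        GrowthObservation(name, ci.observation)
        for name, ci in cfg.conditions.items()
        if ci.observation is not None
    ]

    calibration = None
    if cfg.alpha == "calibrate":
        pairs = [
            (ras_profiles[c], mur_profiles[c])
            for c in conditions
            if ras_profiles[c] is not None and mur_profiles[c] is not None
        ]
        if len(pairs) < 2 or len(observations) < 2:
            raise ConfigError(
                "alpha: calibration needs >=2 conditions with expression, "
                "media and an observation"
            )
        calibration = calibrate(
            gem,
            pairs,
            observations,
            grid=cfg.grid or log_grid(),
            metric=cfg.metric,
        )
        alpha = calibration.selected_alpha
        logger.info("calibrated alpha=%.6g (%s)", alpha, cfg.metric)
    else:
        alpha = float(cfg.alpha)

    biomass = pd.DataFrame(float("nan"), index=conditions, columns=list(cfg.variants))
    status = pd.DataFrame("missing_input", index=conditions, columns=list(cfg.variants))
    fva_rows = []
    for variant in cfg.variants:
        for name in conditions:
            picked = _variant_profiles(
                variant, name, ras_profiles, mur_profiles, cfg.ras_from
            )
            if picked is None:
                logger.info("condition=%s variant=%s skipped (missing input)", name, variant)
                continue
            ras_p, mur_p, effective = picked
            model = build_condition_model(
                gem, ras=ras_p, mur=mur_p,
                cfg=IntegrationConfig(alpha=alpha, variant=effective),
            )
            result = fba(model)
            status.loc[name, variant] = result.status
            biomass.loc[name, variant] = (
                result.objective_value if result.optimal else 0.0
            )
            logger.info(
                "condition=%s variant=%s alpha=%.4g status=%s objective=%s",
                name, variant, alpha, result.status,
                f"{result.objective_value:.6g}" if result.optimal else "-",
            )
            combined = variant in ("ras_mur", "ras_donor_mur")
            if combined and result.optimal and result.objective_value > 1e-12:
                queried = list(cfg.fva_reactions) or (
                    sorted(mur_p.rates) if mur_p is not None else []
                )
                if queried:
                    fva_result = run_fva(model, queried, gamma=cfg.gamma)
                    for rid, (lo, hi) in fva_result.intervals.items():
                        fva_rows.append((name, variant, rid, lo, hi))

    fva_frame = pd.DataFrame(
        fva_rows, columns=["condition", "variant", "reaction_id", "min_flux", "max_flux"]
    )
    provenance = {
        "software": f"gemprofiler {_version}",
        "seed": cfg.seed,
        "alpha": alpha,
        "gamma": cfg.gamma,
        "metric": cfg.metric,
        "model": {"path": str(cfg.model), "sha256": _sha256(cfg.model)},
        "inputs": {
            name: {
                fld: ({"path": p, "sha256": _sha256(p)} if (p := getattr(ci, fld)) else None)
                for fld in ("expression", "media")
            }
            for name, ci in cfg.conditions.items()
        },
    }
    report = ProfilingReport(
        biomass=biomass,
        status=status,
        fva=fva_frame,
        calibration=calibration,
        alpha=alpha,
        gamma=cfg.gamma,
        provenance=provenance,
    )
    if cfg.outdir:
        report.write(cfg.outdir)
    return report
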