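"""Seeded toy-scale generators for every pipeline input.

The generated study emulates a nutrient-availability experiment on a
cultured cell line: a small metabolic network with exchange reactions for a
handful of medium nutrients, GPR rules on internal reactions, a biomass
sink, negative-binomial expression counts (three replicates per condition),
a media table varying two nutrient concentrations across conditions
(including zero-availability conditions), and growth observations
forward-simulated from the model itself at a known ground-truth alpha.

Topology is structured rather than fully random so that the biology of the
study design is reproduced: one nutrient (the glutamine analogue ``gln_e``)
is the only source of biomass precursor ``p2_c`` and can also feed ``p1_c``
(as glutaminolysis feeds both energy and biosynthesis pools), while the
glucose analogue ``glc_e`` feeds only ``p1_c``.  Growth is therefore
glutamine-dependent and glucose-independent, and zero-glutamine conditions
cannot grow.  Random extra conversions, reversibilities and GPR forms are
layered on top for variety; everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import fba
from .calibration import GrowthObservation
from .integration import IntegrationConfig, build_condition_model
from .model import GEM, Reaction, write_model
from .mur import MediumMeasurement, MURProfile, build_mur_profile
from .ras import RASProfile, aggregate_expression, compute_ras_profile

__all__ = [
    "FixtureSpec",
    "StudyBundle",
    "make_toy_gem",
    "make_media",
    "make_expression_counts",
    "simulate_growth_observations",
    "make_study",
    "write_fixtures",
]

# paper-style two-nutrient design: (name, glucose-like mM, glutamine-like mM)
_CONDITION_TEMPLATE = (
    ("Glc10Gln4", 10.0, 4.0),
    ("Glc2Gln4", 2.0, 4.0),
    ("Glc10Gln0", 10.0, 0.0),
    ("Glc2Gln0", 2.0, 0.0),
    ("Glc25Gln4", 25.0, 4.0),
    ("Glc2Gln0.5", 2.0, 0.5),
    ("Glc2Gln2", 2.0, 2.0),
)

_AUX_CONC_MM = 10.0
_DEFAULT_UPTAKE = 1000.0  # Recon-style wide default; MUR can only tighten it
_BIG = 1000.0


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic experiment.

    Defaults mirror the real design: 7 media conditions over two nutrients
    (with zero-availability conditions), 3 replicates, 5% multiplicative
    noise on the growth observable.  ``true_alpha`` sits on the default
    calibration grid inside the per-condition saturation cascade — above
    the knee of the low-availability conditions, below that of the rich
    ones (CPM-scale scores of a few 1e4 against uptake caps of 0.5-25
    mM/48 h put the cascade near 1e-5..3e-4) — which is what makes the
    calibration identifiable.
    """

    seed: int = 0
    n_metabolites: int = 10
    n_internal_reactions: int = 8
    n_exchange: int = 4
    genes_per_reaction: tuple[int, int] = (1, 4)
    reversible_fraction: float = 0.3
    n_conditions: int = 7
    n_replicates: int = 3
    noise_cv: float = 0.05
    true_alpha: float = 10.0 ** -4.25

    def __post_init__(self) -> None:
        if min(self.n_metabolites, self.n_internal_reactions, self.n_exchange) < 1:
            raise ValueError("counts must be positive")
        if self.n_exchange + self.n_internal_reactions + 1 > 30:
            raise ValueError("toy models are capped at 30 reactions")
        if not 0 <= self.reversible_fraction <= 1:
            raise ValueError("reversible_fraction must lie in [0, 1]")
        if self.noise_cv < 0 or self.true_alpha <= 0:
            raise ValueError("noise_cv must be >= 0 and true_alpha > 0")

    # nutrient layout is deterministic in the spec, independent of the rng
    @property
    def nutrient_ids(self) -> tuple[str, ...]:
        n = max(1, self.n_exchange - 1)
        names = ["gln_e"]
        if n >= 2:
            names.append("glc_e")
        names += [f"aux{i}_e" for i in range(3, n + 1)]
        return tuple(names)


def _gene_pool(spec: FixtureSpec) -> list[str]:
    size = max(6, 3 * spec.n_internal_reactions)
    return [f"g{i:03d}" for i in range(1, size + 1)]


def _random_gpr(rng: np.random.Generator, pool: Sequence[str], lo: int, hi: int) -> str:
    k = int(rng.integers(lo, hi + 1))
    k = max(1, min(k, len(pool)))
    genes = list(rng.choice(pool, size=k, replace=False))
    if k == 1:
        return genes[0]
    if k == 2:
        op = " and " if rng.random() < 0.5 else " or "
        return op.join(genes)
    if k == 3:
        form = rng.integers(0, 3)
        if form == 0:
            return f"({genes[0]} and {genes[1]}) or {genes[2]}"
        if form == 1:
            return " and ".join(genes)
        return " or ".join(genes)
    return f"({genes[0]} and {genes[1]}) or ({genes[2]} and {genes[3]})"


def make_toy_gem(spec: FixtureSpec) -> GEM:
    """A growth-capable toy network with GPRs, deterministic per seed."""
    last_error = "no attempts made"
    for attempt in range(20):
        rng = np.random.default_rng([spec.seed, 17, attempt])
        gem = _build_network(spec, rng)
        result = fba(gem)
        if result.optimal and result.objective_value > 1e-6:
            return gem
        last_error = f"attempt {attempt}: biomass optimum {result.objective_value}"
    raise RuntimeError(f"could not generate a growth-capable network: {last_error}")


def _build_network(spec: FixtureSpec, rng: np.random.Generator) -> GEM:
    pool = _gene_pool(spec)
    lo, hi = spec.genes_per_reaction
    nutrients = spec.nutrient_ids
    mets = list(nutrients) + ["lac_e", "p1_c", "p2_c"]
    n_extra_mets = max(0, spec.n_metabolites - len(mets))
    extra_mets = [f"m{i}_c" for i in range(1, n_extra_mets + 1)]
    mets += extra_mets

    reactions: list[Reaction] = []
    for nut in nutrients:
        reactions.append(
            Reaction(f"EX_{nut}", -_DEFAULT_UPTAKE, _BIG, {nut: -1.0})
        )
    reactions.append(Reaction("EX_lac_e", 0.0, _BIG, {"lac_e": -1.0}))

    def internal(rid: str, stoich: dict, reversible: bool = False) -> Reaction:
        return Reaction(
            rid,
            -_BIG if reversible else 0.0,
            _BIG,
            stoich,
            gpr=_random_gpr(rng, pool, lo, hi),
        )

    core = [
        internal("R_GLN_P2", {"gln_e": -1.0, "p2_c": 1.0}),
        internal("R_P2_P1", {"p2_c": -1.0, "p1_c": 1.0}),
        internal("R_P1_LAC", {"p1_c": -1.0, "lac_e": 1.0}),
    ]
    if "glc_e" in nutrients:
        core.append(internal("R_GLC_P1", {"glc_e": -1.0, "p1_c": 1.0}))
    for nut in nutrients:
        if nut.startswith("aux"):
            target = (
                str(rng.choice(extra_mets)) if extra_mets and rng.random() < 0.5
                else "p1_c"
            )
            core.append(internal(f"R_{nut.upper()}", {nut: -1.0, target: 1.0}))
    reactions += core

    # filler conversions on the p1 side only: p2_c stays reachable solely
    # from the glutamine analogue, preserving its essentiality
    p1_side = ["p1_c"] + extra_mets
    n_filler = max(0, spec.n_internal_reactions - len(core))
    for i in range(n_filler):
        if len(p1_side) >= 2:
            a, b = rng.choice(p1_side, size=2, replace=False)
        else:
            a, b = "p1_c", "p1_c"
        if a == b:
            continue
        reversible = bool(rng.random() < spec.reversible_fraction)
        reactions.append(
            internal(f"R_X{i + 1}", {str(a): -1.0, str(b): 1.0}, reversible)
        )

    reactions.append(
        Reaction("BIOMASS_toy", 0.0, _BIG, {"p1_c": -1.0, "p2_c": -1.0})
    )
    return GEM(
        model_id=f"toy_seed{spec.seed}",
        reactions=tuple(reactions),
        metabolites=tuple(mets),
        objective_coefficients={"BIOMASS_toy": 1.0},
    )


def make_media(spec: FixtureSpec) -> pd.DataFrame:
    """Media table over ``n_conditions`` varying the two main nutrients.

    Availability-only mode: final concentrations are 0 (each nutrient may be
    consumed completely over the 48 h window).  Auxiliary nutrients are held
    at a constant concentration in every condition.
    """
    rng = np.random.default_rng([spec.seed, 23])
    conditions: list[tuple[str, float, float]] = list(
        _CONDITION_TEMPLATE[: spec.n_conditions]
    )
    while len(conditions) < spec.n_conditions:
        g = float(rng.choice([2.0, 5.0, 10.0, 25.0]))
        q = float(rng.choice([0.0, 0.5, 1.0, 2.0, 4.0]))
        name = f"Glc{g:g}Gln{q:g}_{len(conditions)}"
        conditions.append((name, g, q))

    nutrients = spec.nutrient_ids
    rows = []
    for name, glc, gln in conditions:
        rows.append((name, "glutamine", "EX_gln_e", gln))
        if "glc_e" in nutrients:
            rows.append((name, "glucose", "EX_glc_e", glc))
        for nut in nutrients:
            if nut.startswith("aux"):
                rows.append((name, nut[:-2], f"EX_{nut}", _AUX_CONC_MM))
    frame = pd.DataFrame(
        rows, columns=["condition", "metabolite", "exchange_id", "conc_initial_mM"]
    )
    frame["conc_final_mM"] = 0.0
    frame["t_hours"] = 48.0
    return frame


def make_expression_counts(
    spec: FixtureSpec,
    gem: GEM,
    conditions: Optional[Sequence[str]] = None,
    mean_scale: float = 1.0,
) -> pd.DataFrame:
    """Negative-binomial counts, genes x (condition, replicate).

    Per-gene base means are lognormal; each condition applies an independent
    lognormal fold change per gene, so activity scores genuinely differ
    across conditions.  Dispersion is fixed (NB size 10).  ``mean_scale``
    multiplies every expected count (sequencing-depth knob): doubling it
    doubles the expected aggregated abundance of every gene.
    """
    from .gpr import gpr_genes, parse_gpr

    genes = sorted(
        {g for r in gem.reactions if r.gpr for g in gpr_genes(parse_gpr(r.gpr))}
    )
    if not genes:
        raise ValueError("model has no GPR genes to simulate expression for")
    if conditions is None:
        conditions = [name for name, _, _ in _CONDITION_TEMPLATE[: spec.n_conditions]]
    rng = np.random.default_rng([spec.seed, 29])
    base = mean_scale * rng.lognormal(mean=math.log(300.0), sigma=1.0, size=len(genes))
    size_param = 10.0
    columns: dict[tuple[str, str], np.ndarray] = {}
    for cond in conditions:
        fold = rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))
        mu = base * fold
        p = size_param / (size_param + mu)
        for rep in range(1, spec.n_replicates + 1):
            columns[(cond, f"rep{rep}")] = rng.negative_binomial(size_param, p)
    frame = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["condition", "replicate"])
    return frame


def simulate_growth_observations(
    gem: GEM,
    condition_profiles: Sequence[tuple[RASProfile, MURProfile]],
    true_alpha: float,
    noise_cv: float,
    seed: int,
    scale: float = 0.005,
) -> list[GrowthObservation]:
    """Forward-simulate reciprocal doubling times from the model itself.

    observation = biomass flux of the combined RAS+MUR condition model at
    ``true_alpha``, times a fixed positive unit-conversion scale (1/h per
    mM/48 h), times multiplicative lognormal noise with the given CV.
    Conditions with (near-)zero flux yield an absent observation — no
    growth, no doubling time.
    """
    rng = np.random.default_rng([seed, 31])
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    out = []
    for ras_p, mur_p in condition_profiles:
        model = build_condition_model(
            gem, ras=ras_p, mur=mur_p, cfg=IntegrationConfig(alpha=true_alpha)
        )
        result = fba(model)
        z = result.objective_value if result.optimal else 0.0
        noise = rng.lognormal(mean=0.0, sigma=sigma) if sigma else 1.0
        if z <= 1e-9:
            out.append(GrowthObservation(ras_p.condition, None))
        else:
            out.append(GrowthObservation(ras_p.condition, float(z * scale * noise)))
    return out


@dataclass(frozen=True)
class StudyBundle:
    """Everything one synthetic study produces, ready for calibration."""

    spec: FixtureSpec
    gem: GEM
    counts: pd.DataFrame
    media: pd.DataFrame
    measurements: dict[str, list[MediumMeasurement]]
    profiles: dict[str, tuple[RASProfile, MURProfile]]
    observations: tuple[GrowthObservation, ...]

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.profiles)

    def condition_profiles(self) -> list[tuple[RASProfile, MURProfile]]:
        return list(self.profiles.values())


def make_study(spec: FixtureSpec) -> StudyBundle:
    """Generate a complete, internally consistent synthetic study."""
    gem = make_toy_gem(spec)
    media = make_media(spec)
    conditions = list(dict.fromkeys(media["condition"]))
    counts = make_expression_counts(spec, gem, conditions)

    measurements: dict[str, list[MediumMeasurement]] = {}
    for cond, group in media.groupby("condition", sort=False):
        measurements[cond] = [
            MediumMeasurement(
                metabolite=str(row.metabolite),
                exchange_reaction_id=str(row.exchange_id),
                conc_initial=float(row.conc_initial_mM),
                conc_final=float(row.conc_final_mM),
                t_final=float(row.t_hours),
            )
            for row in group.itertuples()
        ]

    profiles: dict[str, tuple[RASProfile, MURProfile]] = {}
    for cond in conditions:
        abundances = aggregate_expression(counts[cond], "cpm", "mean")
        ras_p = compute_ras_profile(gem, abundances, condition=cond)
        mur_p = build_mur_profile(cond, measurements[cond], gem)
        profiles[cond] = (ras_p, mur_p)

    observations = simulate_growth_observations(
        gem,
        list(profiles.values()),
        true_alpha=spec.true_alpha,
        noise_cv=spec.noise_cv,
        seed=spec.seed,
    )
    return StudyBundle(
        spec=spec,
        gem=gem,
        counts=counts,
        media=media,
        measurements=measurements,
        profiles=profiles,
        observations=tuple(observations),
    )


def write_fixtures(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Write the whole study to disk (model, expression, media, observations)."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = make_study(spec)
    paths: dict[str, Path] = {}

    paths["model_json"] = outdir / "model.json"
    paths["model_sbml"] = outdir / "model.xml"
    write_model(study.gem, paths["model_json"])
    write_model(study.gem, paths["model_sbml"])

    for cond in study.conditions:
        p = outdir / f"expression_{cond}.tsv"
        table = study.counts[cond].copy()
        table.insert(0, "gene", table.index)
        table.to_csv(p, sep="\t", index=False)
        paths[f"expression_{cond}"] = p

    paths["media"] = outdir / "media.tsv"
    study.media.to_csv(paths["media"], sep="\t", index=False)

    paths["observations"] = outdir / "observations.yaml"
    obs = {
        o.condition: (
            None
            if o.reciprocal_doubling_time is None
            else float(o.reciprocal_doubling_time)
        )
        for o in study.observations
    }
    with open(paths["observations"], "w") as fh:
        yaml.safe_dump({"reciprocal_doubling_time_per_h": obs}, fh)
    return paths
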