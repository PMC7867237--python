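"""Genome-scale metabolic model container, I/O and structural queries.

The in-memory representation is a small immutable :class:`GEM` holding the
stoichiometry, per-reaction flux bounds, gene-protein-reaction (GPR) rule
strings and the linear objective.  File I/O (SBML Level 3 + FBC and
COBRA-JSON) is delegated to cobrapy; the container itself stays independent
of any solver so that condition-specific model variants can be derived as
cheap copies without aliasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "GEM",
    "Reaction",
    "ModelReport",
    "GEMError",
    "ModelFormatError",
    "AmbiguityError",
    "read_model",
    "write_model",
    "find_biomass_reaction",
    "exchange_reactions",
    "model_report",
]


class GEMError(ValueError):
    """Structural problem with a metabolic model."""


class ModelFormatError(GEMError):
    """A model file could not be parsed under the requested standard."""


class AmbiguityError(GEMError):
    """A query (e.g. biomass lookup) has zero or multiple candidates."""


@dataclass(frozen=True)
class Reaction:
    """One reaction: id, flux bounds, stoichiometry and optional GPR rule.

    ``stoich`` maps metabolite id to its stoichiometric coefficient
    (negative = consumed).  A boundary (exchange) reaction is one touching
    exactly one metabolite, following the COBRA convention for ``EX_``
    pseudo-reactions regardless of compartment tags.
    """

    id: str
    lower_bound: float
    upper_bound: float
    stoich: Mapping[str, float]
    gpr: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise GEMError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return sum(1 for c in self.stoich.values() if c != 0) == 1

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=float(lower), upper_bound=float(upper))


@dataclass(frozen=True)
class GEM:
    """An immutable genome-scale metabolic model.

    ``objective_coefficients`` holds only the nonzero entries of the
    objective vector c; integration operations never mutate a GEM in place
    but return modified copies, so condition models never alias.
    """

    model_id: str
    reactions: tuple[Reaction, ...]
    metabolites: tuple[str, ...]
    objective_coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            raise GEMError(f"duplicate reaction ids: {dup}")
        if len(set(self.metabolites)) != len(self.metabolites):
            raise GEMError("duplicate metabolite ids")
        declared = set(self.metabolites)
        for r in self.reactions:
            unknown = set(r.stoich) - declared
            if unknown:
                raise GEMError(
                    f"reaction {r.id!r} references undeclared metabolites: "
                    f"{sorted(unknown)}"
                )
        unknown_obj = set(self.objective_coefficients) - set(rids)
        if unknown_obj:
            raise GEMError(
                f"objective references unknown reactions: {sorted(unknown_obj)}"
            )

    # -- structural queries -------------------------------------------------

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S as a sparse (n_metabolites x n_reactions) matrix in model order."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich.items():
                if c != 0:
                    rows.append(met_index[m])
                    cols.append(j)
                    vals.append(float(c))
        return sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        for j, r in enumerate(self.reactions):
            c[j] = self.objective_coefficients.get(r.id, 0.0)
        return c

    def with_reactions(self, reactions: Iterable[Reaction]) -> "GEM":
        return replace(self, reactions=tuple(reactions))


@dataclass(frozen=True)
class ModelReport:
    """Summary counts of a model, for quick inspection."""

    model_id: str
    n_reactions: int
    n_metabolites: int
    n_gpr_reactions: int
    n_exchange: int
    biomass_id: Optional[str]
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n_reactions": self.n_reactions,
            "n_metabolites": self.n_metabolites,
            "n_gpr_reactions": self.n_gpr_reactions,
            "n_exchange": self.n_exchange,
            "biomass_id": self.biomass_id,
            "warnings": list(self.warnings),
        }


# -- conversion to / from cobrapy ------------------------------------------


def _from_cobra(model) -> GEM:
    from cobra.util.solver import linear_reaction_coefficients

    used_notes_gpr = False
    reactions = []
    for r in model.reactions:
        gpr = r.gene_reaction_rule or None
        if gpr is None:
            # legacy distributions carry the rule in notes, not FBC
            note = r.notes.get("GENE_ASSOCIATION") or r.notes.get("GENE ASSOCIATION")
            if note and str(note).strip():
                gpr = str(note).strip()
                used_notes_gpr = True
        reactions.append(
            Reaction(
                id=r.id,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                stoich={m.id: float(c) for m, c in r.metabolites.items()},
                gpr=gpr,
            )
        )
    if used_notes_gpr:
        warnings.warn(
            f"model {model.id!r}: GPR rules recovered from notes fields "
            "(no FBC gene associations found)",
            stacklevel=3,
        )
    objective = {
        r.id: float(c) for r, c in linear_reaction_coefficients(model).items() if c
    }
    return GEM(
        model_id=model.id or "model",
        reactions=tuple(reactions),
        metabolites=tuple(m.id for m in model.metabolites),
        objective_coefficients=objective,
    )


def _compartment_of(met_id: str) -> str:
    # Recon/BiGG-style ids carry the compartment as a short suffix ("_e",
    # "[c]"); default to cytosol when no tag is recognisable.
    if met_id.endswith("]") and "[" in met_id:
        return met_id[met_id.rindex("[") + 1 : -1] or "c"
    tail = met_id.rsplit("_", 1)
    if len(tail) == 2 and 1 <= len(tail[1]) <= 2 and tail[1].isalpha():
        return tail[1]
    return "c"


def _to_cobra(gem: GEM):
    import cobra
    from cobra.util.solver import set_objective

    model = cobra.Model(gem.model_id)
    mets = {
        m: cobra.Metabolite(m, compartment=_compartment_of(m))
        for m in gem.metabolites
    }
    crxns = []
    for r in gem.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        crxns.append(cr)
    model.add_reactions(crxns)
    for r, cr in zip(gem.reactions, crxns):
        cr.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    if gem.objective_coefficients:
        set_objective(
            model,
            {
                model.reactions.get_by_id(rid): c
                for rid, c in gem.objective_coefficients.items()
            },
        )
    return model


# -- operations -------------------------------------------------------------


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ModelFormatError(
        f"cannot infer model format from extension {suffix!r}; pass format="
    )


def read_model(path, format: str = "auto") -> GEM:
    """Read an SBML (L3+FBC) or COBRA-JSON model into a :class:`GEM`.

    GPR rule strings and bounds are preserved as stored in the file (modulo
    cobrapy's canonical ``and``/``or`` spelling, which is idempotent).
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt == "sbml":
                model = cobra.io.read_sbml_model(str(path))
            elif fmt == "json":
                model = cobra.io.load_json_model(str(path))
            else:
                raise ModelFormatError(f"unknown format {fmt!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap parser diversity
        raise ModelFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    return _from_cobra(model)


def write_model(gem: GEM, path, format: str = "auto") -> None:
    """Write a :class:`GEM` to SBML or COBRA-JSON.

    Round trip contract: ``read_model(write_model(gem))`` reproduces ids,
    bounds (to 1e-9), every S entry and GPR strings.
    """
    import cobra.io

    path = Path(path)
    fmt = _detect_format(path, format)
    if not gem.objective_coefficients:
        warnings.warn(
            f"model {gem.model_id!r} has an empty objective; FBA will need a "
            "biomass hint",
            stacklevel=2,
        )
    model = _to_cobra(gem)
    try:
        if fmt == "sbml":
            cobra.io.write_sbml_model(model, str(path))
        elif fmt == "json":
            cobra.io.save_json_model(model, str(path))
        else:
            raise ModelFormatError(f"unknown format {fmt!r}")
    except ModelFormatError:
        raise
    except OSError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ModelFormatError(f"could not write {path} as {fmt}: {exc}") from exc


def find_biomass_reaction(gem: GEM, hint: Optional[str] = None) -> str:
    """Identify the biomass/objective reaction.

    Preference order: the unique reaction with a nonzero objective
    coefficient; otherwise the unique reaction whose id contains ``hint``
    (default substring ``"biomass"``, case-insensitive).
    """
    objective = [rid for rid, c in gem.objective_coefficients.items() if c]
    if len(objective) == 1:
        return objective[0]
    if len(objective) > 1:
        raise AmbiguityError(
            f"multiple objective reactions: {sorted(objective)}; "
            "pass an explicit hint"
        )
    pattern = (hint or "biomass").lower()
    matches = [r.id for r in gem.reactions if pattern in r.id.lower()]
    if len(matches) == 1:
        return matches[0]
    raise AmbiguityError(
        f"no unique biomass reaction: objective empty and {len(matches)} ids "
        f"match {pattern!r} ({sorted(matches)})"
    )


def exchange_reactions(gem: GEM) -> list[str]:
    """Ids of boundary (single-metabolite) reactions, in model order."""
    return [r.id for r in gem.reactions if r.is_exchange]


def model_report(gem: GEM) -> ModelReport:
    notes = []
    try:
        biomass = find_biomass_reaction(gem)
    except AmbiguityError as exc:
        biomass = None
        notes.append(str(exc))
    return ModelReport(
        model_id=gem.model_id,
        n_reactions=len(gem.reactions),
        n_metabolites=len(gem.metabolites),
        n_gpr_reactions=sum(1 for r in gem.reactions if r.gpr),
        n_exchange=sum(1 for r in gem.reactions if r.is_exchange),
        biomass_id=biomass,
        warnings=tuple(notes),
    )
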