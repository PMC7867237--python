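"""Reaction Activity Scores (RAS) from gene-expression tables.

A RAS quantifies the transcriptional support of a reaction: its GPR rule is
evaluated numerically on per-gene abundances (AND -> min across complex
subunits, OR -> sum across isozymes).  Reactions without a GPR carry no
score and are left unconstrained downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .gpr import GPRParseError, evaluate_ras, gpr_genes, parse_gpr
from .model import GEM

__all__ = [
    "RASProfile",
    "aggregate_expression",
    "compute_ras_profile",
    "read_expression_table",
    "read_ras_profile",
    "write_ras_profile",
    "strip_gene_version",
]

_VERSION_RE = re.compile(r"\.\d+$")


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing Ensembl-style version suffix (``ENSG...\\.12``)."""
    return _VERSION_RE.sub("", gene_id)


@dataclass(frozen=True)
class RASProfile:
    """Per-reaction activity scores for one culture condition.

    ``coverage`` is the fraction of GPR-bearing reactions in the model for
    which at least one of the rule's genes was measured.
    """

    condition: str
    scores: Mapping[str, float]
    coverage: float

    def __post_init__(self) -> None:
        bad = {r: v for r, v in self.scores.items() if v < 0}
        if bad:
            raise ValueError(f"negative RAS values: {bad}")

    def __len__(self) -> int:
        return len(self.scores)


def aggregate_expression(
    counts: pd.DataFrame,
    normalization: str = "cpm",
    combine: str = "mean",
) -> dict[str, float]:
    """Collapse a gene x replicate count table into one abundance per gene.

    ``normalization="cpm"`` rescales each replicate column to counts per
    million before combining, removing library-depth artefacts while keeping
    within-sample proportions; ``combine`` is the across-replicate summary.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty expression table")
    values = counts.astype(float)
    if (values.to_numpy() < 0).any():
        raise ValueError("negative counts in expression table")
    if normalization == "cpm":
        totals = values.sum(axis=0)
        totals = totals.replace(0, 1.0)
        values = values / totals * 1e6
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    if combine == "mean":
        agg = values.mean(axis=1)
    elif combine == "median":
        agg = values.median(axis=1)
    else:
        raise ValueError(f"unknown combine {combine!r}")
    return {str(g): float(v) for g, v in agg.items()}


def compute_ras_profile(
    gem: GEM,
    abundances: Mapping[str, float],
    missing_policy: str = "skip",
    condition: str = "",
    id_map: Optional[Mapping[str, str]] = None,
) -> RASProfile:
    """Evaluate every GPR-bearing reaction of ``gem`` on ``abundances``.

    Gene ids are matched exactly after stripping ``.N`` version suffixes;
    ``id_map`` optionally translates expression-table ids to model gene ids
    first.  Reactions whose evaluation is undefined under
    ``missing_policy="skip"`` are absent from the profile (their bounds are
    later left untouched).
    """
    lookup: dict[str, float] = {}
    for gene, value in abundances.items():
        key = strip_gene_version(str(gene))
        if id_map and key in id_map:
            key = id_map[key]
        lookup[key] = float(value)

    scores: dict[str, float] = {}
    n_gpr = 0
    n_covered = 0
    for reaction in gem.reactions:
        if not reaction.gpr:
            continue
        n_gpr += 1
        try:
            tree = parse_gpr(reaction.gpr)
        except GPRParseError as exc:
            raise GPRParseError(
                f"reaction {reaction.id!r}: {exc}", exc.offset
            ) from exc
        genes = {strip_gene_version(g) for g in gpr_genes(tree)}
        if genes & lookup.keys():
            n_covered += 1
        value = evaluate_ras(_rename(tree), lookup, missing_policy)
        if value is not None:
            scores[reaction.id] = value
    coverage = n_covered / n_gpr if n_gpr else 0.0
    return RASProfile(condition=condition, scores=scores, coverage=coverage)


def _rename(tree):
    from .gpr import And, Gene, Or

    if isinstance(tree, Gene):
        return Gene(strip_gene_version(tree.name))
    children = tuple(_rename(c) for c in tree.children)
    return And(children) if isinstance(tree, And) else Or(children)


# -- I/O --------------------------------------------------------------------


_FEATURECOUNTS_META = {"chr", "start", "end", "strand", "length"}


def read_expression_table(path) -> pd.DataFrame:
    """Read a gene x replicate expression table (TSV/CSV).

    First column is the gene id, remaining columns one replicate each.
    featureCounts output is accepted: ``#`` comment lines are skipped and
    the Chr/Start/End/Strand/Length annotation columns are dropped.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected gene id plus >=1 replicate column")
    table = table.set_index(table.columns[0])
    drop = [c for c in table.columns if c.strip().lower() in _FEATURECOUNTS_META]
    table = table.drop(columns=drop)
    if table.shape[1] == 0:
        raise ValueError(f"{path}: no count columns after removing annotation")
    return table


def write_ras_profile(profile: RASProfile, path) -> None:
    """Export as two-column TSV (reaction_id, ras)."""
    frame = pd.DataFrame(
        {"reaction_id": list(profile.scores), "ras": list(profile.scores.values())}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_ras_profile(path, condition: str = "") -> RASProfile:
    frame = pd.read_csv(path, sep="\t")
    scores = dict(zip(frame["reaction_id"].astype(str), frame["ras"].astype(float)))
    return RASProfile(condition=condition, scores=scores, coverage=float("nan"))
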