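import json

import pytest

from gemprofiler import (
    GEM,
    AmbiguityError,
    GEMError,
    Reaction,
    exchange_reactions,
    find_biomass_reaction,
    model_report,
    read_model,
    write_model,
)


def _roundtrip(gem, tmp_path, fmt):
    path = tmp_path / f"model.{'xml' if fmt == 'sbml' else 'json'}"
    write_model(gem, path)
    return read_model(path)


@pytest.mark.parametrize("fmt", ["sbml", "json"])
def test_roundtrip_preserves_structure(toy3_gem, tmp_path, fmt):
    back = _roundtrip(toy3_gem, tmp_path, fmt)
    assert back.reaction_ids == toy3_gem.reaction_ids
    assert back.metabolites == toy3_gem.metabolites
    for orig, new in zip(toy3_gem.reactions, back.reactions):
        assert new.lower_bound == pytest.approx(orig.lower_bound, abs=1e-9)
        assert new.upper_bound == pytest.approx(orig.upper_bound, abs=1e-9)
        assert new.stoich == orig.stoich
        assert new.gpr == orig.gpr
    assert dict(back.objective_coefficients) == dict(toy3_gem.objective_coefficients)


def test_sbml_and_json_readers_agree(toy3_gem, tmp_path):
    from_sbml = _roundtrip(toy3_gem, tmp_path, "sbml")
    from_json = _roundtrip(toy3_gem, tmp_path, "json")
    assert from_sbml.reaction_ids == from_json.reaction_ids
    assert [r.stoich for r in from_sbml.reactions] == [
        r.stoich for r in from_json.reactions
    ]
    assert [
        (r.lower_bound, r.upper_bound) for r in from_sbml.reactions
    ] == [(r.lower_bound, r.upper_bound) for r in from_json.reactions]


def test_modified_bounds_survive_roundtrip(toy3_gem, tmp_path):
    tightened = toy3_gem.with_reactions(
        [r.with_bounds(-0.01, 0.01) if r.id == "EX_A_e" else r for r in toy3_gem.reactions]
    )
    back = _roundtrip(tightened, tmp_path, "json")
    ex = back.reaction("EX_A_e")
    assert (ex.lower_bound, ex.upper_bound) == (-0.01, 0.01)


def test_inverted_bounds_rejected():
    with pytest.raises(GEMError, match="lower bound"):
        Reaction("bad", 5.0, -5.0, {"A": -1.0})


def test_unparsable_file_raises_format_error(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text("{not json")
    from gemprofiler import ModelFormatError

    with pytest.raises(ModelFormatError):
        read_model(path)


def test_undeclared_metabolite_rejected():
    with pytest.raises(GEMError, match="undeclared"):
        GEM(
            model_id="bad",
            reactions=(Reaction("R", 0.0, 1.0, {"ghost": -1.0}),),
            metabolites=("real",),
        )


def test_empty_objective_write_warns(toy3_gem, tmp_path):
    no_obj = GEM(
        model_id=toy3_gem.model_id,
        reactions=toy3_gem.reactions,
        metabolites=toy3_gem.metabolites,
        objective_coefficients={},
    )
    with pytest.warns(UserWarning, match="empty objective"):
        write_model(no_obj, tmp_path / "m.json")


class TestBiomassLookup:
    def test_objective_reaction_wins(self, toy3_gem):
        assert find_biomass_reaction(toy3_gem) == "BIOMASS_toy"

    def test_name_fallback_without_objective(self, toy3_gem):
        no_obj = GEM(
            model_id="x",
            reactions=toy3_gem.reactions,
            metabolites=toy3_gem.metabolites,
        )
        assert find_biomass_reaction(no_obj) == "BIOMASS_toy"

    def test_two_biomass_names_ambiguous(self):
        gem = GEM(
            model_id="x",
            reactions=(
                Reaction("biomass_a", 0.0, 1.0, {"A": -1.0}),
                Reaction("biomass_b", 0.0, 1.0, {"A": 1.0}),
            ),
            metabolites=("A",),
        )
        with pytest.raises(AmbiguityError):
            find_biomass_reaction(gem)


class TestExchangeDetection:
    def test_boundary_reactions_found_in_order(self, toy3_gem):
        assert exchange_reactions(toy3_gem) == ["EX_A_e", "BIOMASS_toy"]

    def test_no_boundary_reactions(self):
        gem = GEM(
            model_id="x",
            reactions=(Reaction("R", -1.0, 1.0, {"A": -1.0, "B": 1.0}),),
            metabolites=("A", "B"),
        )
        assert exchange_reactions(gem) == []

    def test_demand_reaction_grows_list(self, toy3_gem):
        extended = GEM(
            model_id="x",
            reactions=toy3_gem.reactions
            + (Reaction("DM_A_c", 0.0, 1000.0, {"A_c": -1.0}),),
            metabolites=toy3_gem.metabolites,
            objective_coefficients=toy3_gem.objective_coefficients,
        )
        assert len(exchange_reactions(extended)) == len(exchange_reactions(toy3_gem)) + 1

    def test_invariant_under_reordering(self, toy3_gem):
        reordered = GEM(
            model_id="x",
            reactions=tuple(reversed(toy3_gem.reactions)),
            metabolites=toy3_gem.metabolites,
            objective_coefficients=toy3_gem.objective_coefficients,
        )
        assert set(exchange_reactions(reordered)) == set(exchange_reactions(toy3_gem))


def test_model_report_counts(toy3_gem):
    report = model_report(toy3_gem)
    assert report.n_reactions == 3
    assert report.n_metabolites == 2
    assert report.n_gpr_reactions == 1
    assert report.n_exchange == 2
    assert report.biomass_id == "BIOMASS_toy"
    assert json.dumps(report.to_dict())  # serialisable


def test_notes_field_gpr_fallback_with_warning():
    import cobra

    from gemprofiler.model import _from_cobra

    model = cobra.Model("legacy")
    met = cobra.Metabolite("A_c", compartment="c")
    rxn = cobra.Reaction("R1")
    rxn.bounds = (0.0, 1000.0)
    model.add_reactions([rxn])
    rxn.add_metabolites({met: -1.0})
    rxn.notes["GENE_ASSOCIATION"] = "gA or gB"
    with pytest.warns(UserWarning, match="notes"):
        gem = _from_cobra(model)
    assert gem.reaction("R1").gpr == "gA or gB"
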