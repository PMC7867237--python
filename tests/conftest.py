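import pytest

from gemprofiler import GEM, Reaction
from gemprofiler.fixtures import FixtureSpec, make_study


@pytest.fixture
def toy3_gem() -> GEM:
    """Three reactions, two metabolites: uptake -> transport(GPR) -> biomass."""
    return GEM(
        model_id="toy3",
        reactions=(
            Reaction("EX_A_e", -5.0, 1000.0, {"A_e": -1.0}),
            Reaction("T_A", 0.0, 1000.0, {"A_e": -1.0, "A_c": 1.0},
                     gpr="(gA and gB) or gC"),
            Reaction("BIOMASS_toy", 0.0, 1000.0, {"A_c": -1.0}),
        ),
        metabolites=("A_e", "A_c"),
        objective_coefficients={"BIOMASS_toy": 1.0},
    )


@pytest.fixture
def chain_gem() -> GEM:
    """Linear chain EX_A(lb=-5) -> A -> B -> biomass; optimum is 5."""
    return GEM(
        model_id="chain",
        reactions=(
            Reaction("EX_A_e", -5.0, 1000.0, {"A_e": -1.0}),
            Reaction("R1", 0.0, 1000.0, {"A_e": -1.0, "B_c": 1.0}, gpr="gA and gB"),
            Reaction("BIOMASS", 0.0, 1000.0, {"B_c": -1.0}),
        ),
        metabolites=("A_e", "B_c"),
        objective_coefficients={"BIOMASS": 1.0},
    )


@pytest.fixture(scope="session")
def study():
    """One seeded synthetic study at default conditions, shared read-only."""
    return make_study(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def study_spec():
    return FixtureSpec(seed=1)
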