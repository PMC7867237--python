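import numpy as np
import pandas as pd
import pytest

from gemprofiler import fba, read_model
from gemprofiler.fixtures import (
    FixtureSpec,
    make_expression_counts,
    make_media,
    make_study,
    make_toy_gem,
    simulate_growth_observations,
    write_fixtures,
)


class TestToyGem:
    def test_deterministic_per_seed(self):
        spec = FixtureSpec(seed=5)
        assert make_toy_gem(spec) == make_toy_gem(spec)

    def test_different_seeds_differ(self):
        a = make_toy_gem(FixtureSpec(seed=5))
        b = make_toy_gem(FixtureSpec(seed=6))
        assert [r.gpr for r in a.reactions] != [r.gpr for r in b.reactions]

    def test_exchange_count_honoured(self):
        gem = make_toy_gem(FixtureSpec(seed=1, n_exchange=2))
        assert sum(r.is_exchange for r in gem.reactions) == 2

    def test_generated_model_is_valid_and_growth_capable(self):
        gem = make_toy_gem(FixtureSpec(seed=9))
        result = fba(gem)  # relies on gem validation at construction
        assert result.status == "optimal"
        assert result.objective_value > 1e-6

    def test_biomass_consumes_two_precursors(self):
        gem = make_toy_gem(FixtureSpec(seed=1))
        biomass = gem.reaction("BIOMASS_toy")
        assert sum(1 for c in biomass.stoich.values() if c < 0) >= 2

    def test_size_cap_enforced(self):
        with pytest.raises(ValueError, match="30 reactions"):
            FixtureSpec(n_exchange=10, n_internal_reactions=25)


class TestExpressionCounts:
    def test_counts_are_nonnegative_integers_and_deterministic(self):
        spec = FixtureSpec(seed=3)
        gem = make_toy_gem(spec)
        a = make_expression_counts(spec, gem)
        b = make_expression_counts(spec, gem)
        pd.testing.assert_frame_equal(a, b)
        values = a.to_numpy()
        assert (values >= 0).all()
        assert np.issubdtype(values.dtype, np.integer)
        assert a.columns.nlevels == 2  # (condition, replicate)

    def test_doubling_means_doubles_aggregated_abundance(self):
        """Monte-Carlo contract: mean_scale is linear in expectation."""
        base_totals, doubled_totals = [], []
        for seed in range(100):
            spec = FixtureSpec(seed=seed, n_conditions=1)
            gem = make_toy_gem(FixtureSpec(seed=0))
            base_totals.append(
                make_expression_counts(spec, gem).to_numpy().mean()
            )
            doubled_totals.append(
                make_expression_counts(spec, gem, mean_scale=2.0).to_numpy().mean()
            )
        ratio = np.mean(doubled_totals) / np.mean(base_totals)
        assert ratio == pytest.approx(2.0, rel=0.1)


class TestMedia:
    def test_zero_availability_condition_present(self):
        media = make_media(FixtureSpec(seed=1))
        per_condition_min = media.groupby("condition")["conc_initial_mM"].min()
        assert (per_condition_min == 0).any()

    def test_concentrations_nonnegative_and_condition_count(self):
        spec = FixtureSpec(seed=1, n_conditions=5)
        media = make_media(spec)
        assert (media["conc_initial_mM"] >= 0).all()
        assert media["condition"].nunique() == 5

    def test_extra_conditions_generated_beyond_template(self):
        media = make_media(FixtureSpec(seed=1, n_conditions=9))
        assert media["condition"].nunique() == 9


class TestObservations:
    def test_noiseless_observations_proportional_to_forward_model(self, study):
        from gemprofiler import IntegrationConfig, build_condition_model

        noiseless = simulate_growth_observations(
            study.gem, study.condition_profiles(),
            true_alpha=study.spec.true_alpha, noise_cv=0.0, seed=1,
        )
        for obs, (ras_p, mur_p) in zip(noiseless, study.condition_profiles()):
            model = build_condition_model(
                study.gem, ras_p, mur_p,
                IntegrationConfig(alpha=study.spec.true_alpha),
            )
            z = fba(model).objective_value
            if z <= 1e-9:
                assert obs.reciprocal_doubling_time is None
            else:
                assert obs.reciprocal_doubling_time == pytest.approx(0.005 * z)

    def test_zero_availability_conditions_unobserved(self, study):
        dead = {"Glc10Gln0", "Glc2Gln0"}
        for obs in study.observations:
            if obs.condition in dead:
                assert obs.reciprocal_doubling_time is None


class TestStudyContract:
    def test_every_fixture_feeds_its_consumer(self, study):
        """The generated bundle satisfies every downstream precondition."""
        assert set(study.counts.columns.get_level_values(0)) == set(study.conditions)
        for cond, (ras_p, mur_p) in study.profiles.items():
            assert ras_p.condition == cond
            assert len(ras_p) > 0
            assert all(v >= 0 for v in ras_p.scores.values())
            assert all(v >= 0 for v in mur_p.rates.values())
        assert len(study.observations) == len(study.conditions)

    def test_written_fixtures_reload_consistently(self, tmp_path):
        spec = FixtureSpec(seed=7)
        paths = write_fixtures(spec, tmp_path)
        gem = read_model(paths["model_json"])
        original = make_toy_gem(spec)
        # orphan metabolites are dropped on write; reactions round-trip exactly
        assert gem.reactions == original.reactions
        assert dict(gem.objective_coefficients) == dict(original.objective_coefficients)
        again = read_model(paths["model_sbml"])
        assert again.reaction_ids == gem.reaction_ids
        media = pd.read_csv(paths["media"], sep="\t")
        assert media["condition"].nunique() == spec.n_conditions
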