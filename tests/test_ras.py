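import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gemprofiler import (
    GPRParseError,
    aggregate_expression,
    compute_ras_profile,
    evaluate_ras,
    parse_gpr,
    read_expression_table,
)
from gemprofiler.gpr import And, Gene, Or

from _oracles import random_gpr_tuple, ref_eval, render_gpr, tuple_genes


class TestParse:
    def test_parenthesised_precedence(self):
        assert parse_gpr("(gA and gB) or gC") == Or(
            (And((Gene("gA"), Gene("gB"))), Gene("gC"))
        )

    def test_single_gene(self):
        assert parse_gpr("gA") == Gene("gA")

    def test_and_binds_tighter_than_or(self):
        assert parse_gpr("gA or gB and gC") == Or(
            (Gene("gA"), And((Gene("gB"), Gene("gC"))))
        )

    @pytest.mark.parametrize("spelling", ["and", "AND", "&", "&&"])
    def test_operator_spellings(self, spelling):
        assert parse_gpr(f"gA {spelling} gB") == And((Gene("gA"), Gene("gB")))

    @pytest.mark.parametrize(
        "rule", ["gA and or gB", "gA and", "(gA or gB", "gA)", "", "and gA"]
    )
    def test_malformed_rules_rejected(self, rule):
        with pytest.raises(GPRParseError):
            parse_gpr(rule)

    def test_error_carries_offset(self):
        with pytest.raises(GPRParseError) as err:
            parse_gpr("gA and or gB")
        assert err.value.offset == 7


class TestEvaluate:
    EM = {"gA": 5.0, "gB": 3.0, "gC": 2.0}

    @pytest.mark.parametrize(
        "rule, expected",
        [
            ("gA and gB", 3.0),  # complex limited by scarcest subunit
            ("gA or gB", 8.0),  # isozymes add up
            ("(gA and gB) or gC", 5.0),  # min(5,3) + 2
            ("gA", 5.0),
        ],
    )
    def test_min_sum_semantics(self, rule, expected):
        assert evaluate_ras(parse_gpr(rule), self.EM) == expected

    def test_missing_gene_policies(self):
        expr = parse_gpr("gA and gB")
        assert evaluate_ras(expr, {"gA": 5.0}, "skip") == 5.0
        assert evaluate_ras(expr, {"gA": 5.0}, "zero") == 0.0

    def test_all_missing_is_undefined_under_skip(self):
        assert evaluate_ras(parse_gpr("gX or gY"), {}, "skip") is None
        assert evaluate_ras(parse_gpr("gX or gY"), {}, "zero") == 0.0


def test_evaluation_matches_recursive_reference():
    """Parse+evaluate agrees exactly with an independent tuple evaluator."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(8)]
    for _ in range(300):
        tree = random_gpr_tuple(rng, genes, depth=4)
        rule = render_gpr(tree, rng)
        present = [g for g in tuple_genes(tree) if rng.random() < 0.7]
        em = {g: float(rng.integers(0, 50)) for g in present}
        for policy in ("skip", "zero"):
            assert evaluate_ras(parse_gpr(rule), em, policy) == ref_eval(
                tree, em, policy
            )


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    abund=st.dictionaries(
        st.sampled_from(["gA", "gB", "gC", "gD"]),
        st.floats(0, 1e6, allow_nan=False),
        min_size=1,
    ),
    bump=st.floats(0.1, 100.0),
    gene=st.sampled_from(["gA", "gB", "gC", "gD"]),
)
def test_ras_monotone_in_abundance(abund, bump, gene):
    """Raising a measured gene's abundance never lowers any score (min and
    sum are monotone); newly measuring a gene is a different operation."""
    expr = parse_gpr("(gA and gB) or (gC and gD)")
    before = evaluate_ras(expr, abund)
    raised = dict(abund)
    target = gene if gene in abund else next(iter(abund))
    raised[target] = raised[target] + bump
    after = evaluate_ras(expr, raised)
    if before is not None:
        assert after >= before


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    abund=st.dictionaries(
        st.sampled_from(["gA", "gB", "gC"]),
        st.floats(0, 1e6, allow_nan=False),
        min_size=1,
    ),
    k=st.floats(1e-3, 1e3),
)
def test_ras_scale_equivariance(abund, k):
    """Scaling all abundances by k scales every score by k."""
    expr = parse_gpr("(gA and gB) or gC")
    base = evaluate_ras(expr, abund)
    scaled = evaluate_ras(expr, {g: v * k for g, v in abund.items()})
    if base is not None:
        assert scaled == pytest.approx(base * k, rel=1e-9)


class TestAggregate:
    def test_plain_mean(self):
        counts = pd.DataFrame({"r1": [10], "r2": [20], "r3": [30]}, index=["g"])
        assert aggregate_expression(counts, "none", "mean") == {"g": 20.0}

    def test_cpm_identity_at_million_library(self):
        counts = pd.DataFrame({"r1": [10, 999990]}, index=["g", "other"])
        assert aggregate_expression(counts, "cpm", "mean")["g"] == pytest.approx(10.0)

    def test_mean_equals_median_for_two_replicates(self):
        counts = pd.DataFrame({"r1": [1], "r2": [100]}, index=["g"])
        assert aggregate_expression(counts, "none", "mean")["g"] == 50.5
        assert aggregate_expression(counts, "none", "median")["g"] == 50.5

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValueError):
            aggregate_expression(pd.DataFrame())
        with pytest.raises(ValueError):
            aggregate_expression(pd.DataFrame({"r1": [-1]}, index=["g"]))


class TestProfile:
    def test_full_coverage(self, toy3_gem):
        profile = compute_ras_profile(toy3_gem, {"gA": 5, "gB": 3, "gC": 2})
        assert profile.scores == {"T_A": 5.0}
        assert profile.coverage == 1.0

    def test_uncovered_reaction_absent_under_skip(self):
        from gemprofiler import GEM, Reaction

        gem = GEM(
            model_id="two_gpr",
            reactions=(
                Reaction("R1", 0.0, 1.0, {"A": -1.0, "B": 1.0}, gpr="gA and gB"),
                Reaction("R2", 0.0, 1.0, {"B": -1.0, "A": 1.0}, gpr="gZ"),
            ),
            metabolites=("A", "B"),
        )
        profile = compute_ras_profile(gem, {"gA": 5, "gB": 3})
        assert set(profile.scores) == {"R1"}
        assert profile.coverage == 0.5

    def test_version_suffixes_stripped(self, toy3_gem):
        profile = compute_ras_profile(toy3_gem, {"gA.1": 5, "gB.12": 3, "gC.2": 2})
        assert profile.scores == {"T_A": 5.0}

    def test_matches_reference_on_random_model(self, study):
        """Profile equals per-reaction reference evaluation of each rule."""
        from gemprofiler.gpr import gpr_genes

        gem = study.gem
        rng = np.random.default_rng(3)
        genes = sorted({g for r in gem.reactions if r.gpr
                        for g in gpr_genes(parse_gpr(r.gpr))})
        em = {g: float(rng.integers(0, 100)) for g in genes if rng.random() < 0.8}
        profile = compute_ras_profile(gem, em)
        for r in gem.reactions:
            if not r.gpr:
                assert r.id not in profile.scores
                continue
            expected = evaluate_ras(parse_gpr(r.gpr), em)
            if expected is None:
                assert r.id not in profile.scores
            else:
                assert profile.scores[r.id] == expected


def test_featurecounts_table_accepted(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "# Program:featureCounts v2.0\n"
        "Geneid\tChr\tStart\tEnd\tStrand\tLength\ts1.bam\ts2.bam\n"
        "gA\t1\t1\t100\t+\t100\t10\t20\n"
        "gB\t1\t200\t300\t-\t100\t5\t15\n"
    )
    table = read_expression_table(path)
    assert list(table.columns) == ["s1.bam", "s2.bam"]
    assert table.loc["gA", "s1.bam"] == 10
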