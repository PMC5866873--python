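"""Mamdani engine: membership arithmetic, rule base, inference, defuzzification."""

import itertools

import numpy as np
import pytest

from neurotap import (
    FuzzySystem,
    TriangularMF,
    complete_rule_base,
    default_system,
    defuzzify_centroid,
    infer,
    membership,
    stage_label,
)
from neurotap.fuzzy import (
    NoRuleFiredError,
    STAGE_ORDER,
    clipped_triangle_centroid,
    rule_strengths,
)

# The five published rule-base rows.
PUBLISHED_RULES = {
    ("HIGH", "HIGH", "HIGH"): "HEALTHY/PRECLINICAL",
    ("HIGH", "LOW", "HIGH"): "EARLY",
    ("AVERAGE", "AVERAGE", "AVERAGE"): "AVERAGE",
    ("LOW", "LOW", "HIGH"): "LATE",
    ("LOW", "LOW", "LOW"): "ADVANCED",
}


class TestMembership:
    def test_peak_has_full_membership(self):
        assert membership(TriangularMF(0, 2, 4), 2.0) == 1.0

    def test_rising_edge_linear_interpolation(self):
        # HIGH term at 8.47: (8.47 - 6.6) / (8.5 - 6.6)
        assert membership(TriangularMF(6.6, 8.5, 10), 8.47) == pytest.approx(1.87 / 1.9)

    def test_outside_support_is_zero(self):
        mf = TriangularMF(0, 2, 4)
        assert membership(mf, 5.0) == 0.0
        assert membership(mf, -0.1) == 0.0

    def test_degenerate_side_gives_full_membership_at_shared_point(self):
        assert membership(TriangularMF(0, 0, 4), 0.0) == 1.0
        assert membership(TriangularMF(6, 10, 10), 10.0) == 1.0

    def test_vectorized_matches_scalar(self):
        mf = TriangularMF(3.6, 5.5, 7.0)
        xs = np.linspace(0, 10, 101)
        assert membership(mf, xs) == pytest.approx([membership(mf, float(x)) for x in xs])


class TestRuleBase:
    def test_covers_all_27_combinations_exactly_once(self):
        rules = complete_rule_base()
        assert len(rules) == 27
        assert len({r.antecedent for r in rules}) == 27

    def test_reproduces_all_published_rows(self):
        by_antecedent = {r.antecedent: r.consequent for r in complete_rule_base()}
        for antecedent, consequent in PUBLISHED_RULES.items():
            assert by_antecedent[antecedent] == consequent

    def test_completion_is_monotone_in_each_antecedent(self):
        """Raising one antecedent term never lowers the consequent stage."""
        order = {"LOW": 0, "AVERAGE": 1, "HIGH": 2}
        idx = {lab: i for i, lab in enumerate(STAGE_ORDER)}
        by_antecedent = {r.antecedent: r.consequent for r in complete_rule_base()}
        for combo in itertools.product(("LOW", "AVERAGE"), repeat=3):
            for pos in range(3):
                raised = list(combo)
                raised[pos] = {"LOW": "AVERAGE", "AVERAGE": "HIGH"}[combo[pos]]
                assert idx[by_antecedent[tuple(raised)]] >= idx[by_antecedent[combo]]


class TestInference:
    def test_healthy_corner_fires_only_one_rule(self, fls):
        strengths = rule_strengths(fls, (8.47, 8.03, 7.67))
        fired = {r.antecedent: s for r, s in zip(fls.rules, strengths) if s > 0}
        assert set(fired) == {("HIGH", "HIGH", "HIGH")}
        assert fired[("HIGH", "HIGH", "HIGH")] == pytest.approx(
            min(1.87 / 1.9, 1.43 / 1.9, 1.07 / 1.9))

    def test_peak_inputs_recover_the_full_consequent_triangle(self, fls):
        agg = infer(fls, (2.0, 2.0, 2.0))
        grid = fls.grid
        assert agg == pytest.approx(membership(TriangularMF(0, 1, 2), grid))

    def test_aggregate_degrees_stay_in_unit_interval(self, fls):
        rng = np.random.default_rng(0)
        for _ in range(20):
            agg = infer(fls, rng.uniform(0, 10, size=3))
            assert np.all(agg >= 0) and np.all(agg <= 1)

    def test_out_of_domain_inputs_are_clipped_with_warning(self, fls, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="neurotap.fuzzy"):
            s_over, _ = stage_label(fls, (11.0, 8.0, 8.0))
        s_edge, _ = stage_label(fls, (10.0 - fls.grid_step, 8.0, 8.0))
        assert s_over == pytest.approx(s_edge)
        assert any("clipping" in m for m in caplog.messages)


class TestDefuzzification:
    def test_full_triangle_centroid_is_the_vertex_mean(self, fls):
        grid = fls.grid
        agg = membership(TriangularMF(3.5, 5.0, 6.0), grid)
        assert defuzzify_centroid(fls, agg) == pytest.approx((3.5 + 5 + 6) / 3, abs=1e-3)

    def test_symmetric_clipped_triangle_centroid_sits_at_the_peak(self, fls):
        grid = fls.grid
        agg = np.minimum(membership(TriangularMF(2.0, 5.0, 8.0), grid), 0.4)
        assert defuzzify_centroid(fls, agg) == pytest.approx(5.0, abs=1e-3)

    def test_no_rule_fired_raises(self, fls):
        with pytest.raises(NoRuleFiredError):
            defuzzify_centroid(fls, np.zeros_like(fls.grid))

    def test_grid_centroid_matches_analytic_oracle_on_random_activations(self, fls):
        """100 random clipped-triangle aggregates: grid vs trapezoid oracle <= 1e-3."""
        rng = np.random.default_rng(7)
        grid = fls.grid
        terms = [mf for _, mf in fls.output.terms]
        for _ in range(100):
            k = rng.integers(1, 4)
            chosen = rng.choice(len(terms), size=k, replace=False)
            heights = rng.uniform(0.05, 1.0, size=k)
            agg = np.zeros_like(grid)
            pairs = []
            for i, h in zip(chosen, heights):
                agg = np.maximum(agg, np.minimum(membership(terms[i], grid), h))
                pairs.append((terms[i], float(h)))
            assert defuzzify_centroid(fls, agg) == pytest.approx(
                clipped_triangle_centroid(pairs), abs=1e-3)


class TestStageLabel:
    @pytest.mark.parametrize("inputs,rounded,label", [
        ((8.47, 8.03, 7.67), 9, "HEALTHY/PRECLINICAL"),
        ((7.98, 6.70, 6.84), 7, "EARLY"),
        ((5.0, 5.0, 5.0), 5, "AVERAGE"),
    ])
    def test_worked_examples(self, fls, inputs, rounded, label):
        score, stage = stage_label(fls, inputs)
        assert round(score) == rounded
        assert stage == label

    def test_average_corner_activation(self, fls):
        strengths = rule_strengths(fls, (5.0, 5.0, 5.0))
        fired = {r.antecedent: s for r, s in zip(fls.rules, strengths) if s > 0}
        # AVERAGE (3.6, 5.5, 7) rising side at 5: (5 - 3.6) / (5.5 - 3.6)
        assert fired == {("AVERAGE",) * 3: pytest.approx(1.4 / 1.9)}

    def test_stage_is_monotone_under_single_input_raises(self, fls):
        """1000 random triples: raising one input never lowers the ordinal
        reaction stage, and crisp scores stay inside [0, 10].

        The crisp score itself is not exactly monotone: the centroid of a
        clipped asymmetric triangle is non-monotone in the clip height, so
        raising an input past a term's peak can shave a small amount
        (~0.1-0.2 at worst) off the score while the stage is unchanged.
        The ordinal stage — what the two-session verdict consumes — is the
        monotone quantity, so that is the contract asserted here.
        """
        rng = np.random.default_rng(11)
        order = list(STAGE_ORDER)
        for _ in range(1000):
            base = rng.uniform(0.2, 9.5, size=3)
            s0, l0 = stage_label(fls, base)
            assert 0.0 <= s0 <= 10.0
            bumped = base.copy()
            pos = rng.integers(3)
            bumped[pos] = min(bumped[pos] + rng.uniform(0, 2.0), 9.8)
            s1, l1 = stage_label(fls, bumped)
            assert order.index(l1) >= order.index(l0)
            assert 0.0 <= s1 <= 10.0

    def test_score_lies_within_activated_support_hull(self, fls):
        rng = np.random.default_rng(13)
        for _ in range(50):
            vals = rng.uniform(0.5, 9.5, size=3)
            strengths = rule_strengths(fls, vals)
            score, _ = stage_label(fls, vals)
            supports = [fls.output.term(r.consequent)
                        for r, s in zip(fls.rules, strengths) if s > 0]
            assert min(mf.a for mf in supports) <= score <= max(mf.c for mf in supports)


class TestSerialization:
    def test_yaml_round_trip_preserves_inference(self, fls, tmp_path):
        p = tmp_path / "fls.yaml"
        fls.save(p)
        back = FuzzySystem.load(p)
        for inputs in [(8.47, 8.03, 7.67), (3.3, 4.1, 6.2)]:
            assert stage_label(back, inputs) == stage_label(fls, inputs)

    def test_incomplete_rule_base_can_leave_centroid_undefined(self):
        sys27 = default_system()
        partial = FuzzySystem(
            inputs=sys27.inputs, output=sys27.output,
            rules=tuple(r for r in sys27.rules if r.antecedent == ("LOW", "LOW", "LOW")),
        )
        with pytest.raises(NoRuleFiredError):
            stage_label(partial, (9.0, 9.0, 9.0))
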