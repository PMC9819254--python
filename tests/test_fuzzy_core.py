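"""Unit and property tests for the generic Mamdani machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzydose import (
    CENTROID,
    WEIGHTED,
    ConfigurationError,
    DefuzzConfig,
    DomainError,
    FiredRule,
    FuzzyRule,
    MembershipFunction,
    NoApplicableRuleError,
    defuzzify_centroid,
    defuzzify_weighted,
    fire_rules,
    membership_degree,
)

from conftest import truncated_trapezoid_centroid


class TestMembershipDegree:
    @pytest.mark.parametrize(
        "term_label,x,expected",
        [
            ("Normal", 5.42, 0.8),  # falling edge 5.4 -> 5.5
            ("Normal", 4.7, 1.0),  # plateau interior
            ("Low", 4.5, 0.0),  # outside support
            ("Diabetic", 6.95, 0.5),  # midpoint of the 6.9 -> 7.0 ramp
            ("Diabetic", 7.0, 1.0),  # open-right shoulder start
            ("Diabetic", 11.0, 1.0),  # deep in the open shoulder
            ("Low", 3.9, 1.0),  # open-left shoulder edge
            ("Low", 1.0, 1.0),
            ("Low", 4.0, 0.0),  # closed foot
            ("Normal", 4.0, 1.0),  # plateau start, exact at breakpoint
            ("Normal", 5.4, 1.0),  # plateau end
            ("Normal", 3.9, 0.0),  # closed foot
        ],
    )
    def test_blood_sugar_terms(self, diag_system, term_label, x, expected):
        term = diag_system.input("blood_sugar").term(term_label)
        assert membership_degree(term, x) == pytest.approx(expected)

    def test_grades_bounded(self, diag_system, dose_system):
        rng = np.random.default_rng(0)
        for system in (diag_system, dose_system):
            for var in system.inputs + (system.output,):
                xs = rng.uniform(var.universe_lo, var.universe_hi, 200)
                for x in xs:
                    for term in var.terms:
                        assert 0.0 <= membership_degree(term, float(x)) <= 1.0

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ConfigurationError):
            MembershipFunction("bad", 2.0, 1.0, 3.0, 4.0)

    def test_nonfinite_argument_rejected(self, diag_system):
        term = diag_system.input("blood_sugar").term("Normal")
        with pytest.raises(DomainError):
            membership_degree(term, math.nan)


class TestFuzzify:
    def test_heart_rate_crossover(self, diag_system):
        grades = diag_system.input("heart_rate").fuzzify(58.7)
        assert grades == pytest.approx(
            {"Bradycardia": 0.65, "Normal": 0.35, "Tachycardia": 0.0}
        )

    def test_heart_rate_plateau(self, diag_system):
        grades = diag_system.input("heart_rate").fuzzify(80.0)
        assert grades == {"Bradycardia": 0.0, "Normal": 1.0, "Tachycardia": 0.0}

    def test_blood_sugar_crossover_midpoint(self, diag_system):
        grades = diag_system.input("blood_sugar").fuzzify(3.95)
        assert grades == pytest.approx(
            {"Low": 0.5, "Normal": 0.5, "Prediabetic": 0.0, "Diabetic": 0.0}
        )

    def test_out_of_universe_raises_naming_variable(self, diag_system):
        var = diag_system.input("blood_sugar")
        with pytest.raises(DomainError, match=r"blood_sugar.*\[0\.0, 12\.0\]"):
            var.fuzzify(15.0)

    def test_clamp_tolerance(self, diag_system):
        var = diag_system.input("blood_sugar")
        grades = var.fuzzify(12.4, clamp_tolerance=0.5)
        assert grades["Diabetic"] == 1.0
        with pytest.raises(DomainError):
            var.fuzzify(12.6, clamp_tolerance=0.5)

    @settings(max_examples=200, derandomize=True)
    @given(data=st.data())
    def test_partition_of_unity_on_crossovers(
        self, diag_system, dose_system, data
    ):
        """Overlapping adjacent terms sum to exactly 1 on crossover segments."""
        variables = [
            v
            for system in (diag_system, dose_system)
            for v in system.inputs + (system.output,)
        ]
        var = data.draw(st.sampled_from(variables))
        segments = var.crossover_segments()
        left, right, lo, hi = data.draw(st.sampled_from(segments))
        x = data.draw(st.floats(min_value=lo, max_value=hi))
        grades = var.fuzzify(x)
        assert grades[left] + grades[right] == pytest.approx(1.0, abs=1e-9)


class TestFireRules:
    def test_stage1_worked_example_fired_set(self, diag_system):
        fuzzified = {
            "blood_sugar": {"Low": 0.0, "Normal": 0.8, "Prediabetic": 0.2, "Diabetic": 0.0},
            "heart_rate": {"Bradycardia": 0.65, "Normal": 0.35, "Tachycardia": 0.0},
        }
        fired = {f.rule_id: (f.strength, f.consequent)
                 for f in fire_rules(diag_system.rules, fuzzified)}
        assert fired == {
            4: (0.65, "Unhealthy"),
            5: (0.35, "Healthy"),
            7: (0.2, "Unhealthy"),
            8: (0.2, "Unhealthy"),
        }

    def test_single_rule_at_full_strength(self, diag_system):
        fuzzified = {
            "blood_sugar": {"Low": 0.0, "Normal": 1.0, "Prediabetic": 0.0, "Diabetic": 0.0},
            "heart_rate": {"Bradycardia": 0.0, "Normal": 1.0, "Tachycardia": 0.0},
        }
        fired = fire_rules(diag_system.rules, fuzzified)
        assert len(fired) == 1
        assert fired[0].rule_id == 5 and fired[0].strength == 1.0

    def test_all_zero_grades_fire_nothing(self, diag_system):
        fuzzified = {
            "blood_sugar": dict.fromkeys(diag_system.input("blood_sugar").labels, 0.0),
            "heart_rate": dict.fromkeys(diag_system.input("heart_rate").labels, 0.0),
        }
        assert fire_rules(diag_system.rules, fuzzified) == []

    def test_unknown_variable_rejected(self):
        rule = FuzzyRule(1, {"nope": "Low"}, "Unhealthy")
        with pytest.raises(ConfigurationError, match="nope"):
            fire_rules([rule], {"blood_sugar": {"Low": 1.0}})

    def test_unknown_term_rejected(self):
        rule = FuzzyRule(1, {"blood_sugar": "Absurd"}, "Unhealthy")
        with pytest.raises(ConfigurationError, match="Absurd"):
            fire_rules([rule], {"blood_sugar": {"Low": 1.0}})

    def test_strength_monotone_in_antecedent_grades(self, diag_system):
        """Raising any antecedent grade never lowers any rule's strength."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            bs = {l: rng.uniform(0, 1) for l in diag_system.input("blood_sugar").labels}
            hr = {l: rng.uniform(0, 1) for l in diag_system.input("heart_rate").labels}
            base = {f.rule_id: f.strength
                    for f in fire_rules(diag_system.rules, {"blood_sugar": bs, "heart_rate": hr})}
            bumped_label = rng.choice(list(bs))
            bs2 = dict(bs)
            bs2[bumped_label] = min(1.0, bs2[bumped_label] + rng.uniform(0, 0.5))
            bumped = {f.rule_id: f.strength
                      for f in fire_rules(diag_system.rules, {"blood_sugar": bs2, "heart_rate": hr})}
            for rule_id, strength in base.items():
                assert bumped.get(rule_id, 0.0) >= strength - 1e-12


class TestDefuzzifyWeighted:
    CONFIG = DefuzzConfig(WEIGHTED, {"Unhealthy": 40.0, "Healthy": 60.0})

    def test_worked_example(self):
        fired = [
            FiredRule(4, 0.65, "Unhealthy"),
            FiredRule(5, 0.35, "Healthy"),
            FiredRule(7, 0.2, "Unhealthy"),
            FiredRule(8, 0.2, "Unhealthy"),
        ]
        assert defuzzify_weighted(fired, self.CONFIG) == pytest.approx(45.0)

    def test_single_rule_identity(self):
        assert defuzzify_weighted([FiredRule(5, 1.0, "Healthy")], self.CONFIG) == 60.0

    def test_empty_fired_set(self):
        with pytest.raises(NoApplicableRuleError):
            defuzzify_weighted([], self.CONFIG)

    def test_zero_total_strength(self):
        with pytest.raises(NoApplicableRuleError):
            defuzzify_weighted([FiredRule(1, 0.0, "Healthy")], self.CONFIG)

    def test_missing_representative(self):
        with pytest.raises(ConfigurationError):
            defuzzify_weighted(
                [FiredRule(1, 0.5, "Healthy")], DefuzzConfig(WEIGHTED, {"Unhealthy": 40.0})
            )

    def test_result_within_representative_range(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            fired = [FiredRule(i, rng.uniform(0.01, 1), rng.choice(["Unhealthy", "Healthy"]))
                     for i in range(rng.integers(1, 6))]
            out = defuzzify_weighted(fired, self.CONFIG)
            reps = [self.CONFIG.representatives[f.consequent] for f in fired]
            assert min(reps) - 1e-12 <= out <= max(reps) + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(
        strengths=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
        split=st.floats(0.1, 0.9),
    )
    def test_invariant_under_strength_split(self, strengths, split):
        """Duplicating a fired rule with its strength split leaves the output unchanged."""
        fired = [FiredRule(i, s, "Unhealthy" if i % 2 else "Healthy")
                 for i, s in enumerate(strengths)]
        first = fired[0]
        split_fired = [
            FiredRule(100, first.strength * split, first.consequent),
            FiredRule(101, first.strength * (1 - split), first.consequent),
        ] + fired[1:]
        assert defuzzify_weighted(fired, self.CONFIG) == pytest.approx(
            defuzzify_weighted(split_fired, self.CONFIG)
        )


class TestDefuzzifyCentroid:
    def test_single_full_strength_symmetric_trapezoid(self, dose_system):
        out = defuzzify_centroid(
            [FiredRule(14, 1.0, "Medium")], dose_system.output, DefuzzConfig(CENTROID)
        )
        assert out == pytest.approx(25.0, abs=1e-9)

    def test_clipping_preserves_symmetry(self, dose_system):
        out = defuzzify_centroid(
            [FiredRule(14, 0.5, "Medium")], dose_system.output, DefuzzConfig(CENTROID)
        )
        assert out == pytest.approx(25.0, abs=1e-9)

    def test_mixed_firing_matches_fine_grid_oracle(self, dose_system):
        """Aggregate of clipped Low + Medium vs brute-force integration at 1e-4."""
        fired = [FiredRule(1, 0.4, "Low"), FiredRule(5, 0.5, "Medium")]
        out = defuzzify_centroid(fired, dose_system.output, DefuzzConfig(CENTROID))

        var = dose_system.output
        xs = np.arange(var.universe_lo, var.universe_hi + 1e-4 / 2, 1e-4)
        low = np.minimum([var.term("Low")(x) for x in xs], 0.4)
        med = np.minimum([var.term("Medium")(x) for x in xs], 0.5)
        mu = np.maximum(low, med)
        oracle = float(np.trapezoid(xs * mu, xs) / np.trapezoid(mu, xs))
        assert out == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("strengths", [(0.3, 0.7), (1.0, 0.2), (0.5, 0.5)])
    def test_grid_refinement_stability(self, dose_system, strengths):
        """Halving/tenth-ing the grid step moves the centroid by at most 10*step."""
        fired = [FiredRule(1, strengths[0], "Low"), FiredRule(9, strengths[1], "High")]
        coarse = defuzzify_centroid(
            fired, dose_system.output, DefuzzConfig(CENTROID, grid_step=0.01)
        )
        fine = defuzzify_centroid(
            fired, dose_system.output, DefuzzConfig(CENTROID, grid_step=0.001)
        )
        assert abs(coarse - fine) < 10 * 0.01

    def test_single_rule_matches_analytic_centroid(self, diag_system, dose_system):
        """Full-strength single firings equal the closed-form trapezoid centroid."""
        for system in (diag_system, dose_system):
            var = system.output
            for term in var.terms:
                out = defuzzify_centroid(
                    [FiredRule(1, 1.0, term.label)], var, DefuzzConfig(CENTROID)
                )
                expected = truncated_trapezoid_centroid(
                    term, var.universe_lo, var.universe_hi
                )
                assert out == pytest.approx(expected, abs=1e-3), term.label

    def test_empty_fired_set(self, dose_system):
        with pytest.raises(NoApplicableRuleError):
            defuzzify_centroid([], dose_system.output, DefuzzConfig(CENTROID))

    def test_result_inside_universe(self, dose_system):
        rng = np.random.default_rng(7)
        labels = dose_system.output.labels
        for _ in range(20):
            fired = [FiredRule(i, rng.uniform(0.05, 1), rng.choice(labels))
                     for i in range(rng.integers(1, 5))]
            out = defuzzify_centroid(fired, dose_system.output, DefuzzConfig(CENTROID))
            assert dose_system.output.universe_lo <= out <= dose_system.output.universe_hi
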