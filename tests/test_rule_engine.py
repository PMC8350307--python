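import random

import pytest
from hypothesis import given, settings, strategies as st

from rhinoguide.patient_model import DiagnosisCategory, TriState
from rhinoguide.rule_engine import (
    ConfigurationError,
    Course,
    Rule,
    RuleSet,
    classify_course,
    count_abrs_signs,
    fire_rules,
    infer,
    meets_abrs_temporal_criterion,
)

from conftest import make_profile, profile_grid
from _flat_oracle import flat_classify


class TestClassifyCourse:
    @pytest.mark.parametrize(
        "days,expected",
        [
            (0, Course.ACUTE),
            (30, Course.ACUTE),
            (83, Course.ACUTE),
            (84, Course.CHRONIC),  # exactly 12 weeks falls on the chronic side
            (90, Course.CHRONIC),
            (365, Course.CHRONIC),
        ],
    )
    def test_twelve_week_boundary(self, days, expected):
        assert classify_course(days) is expected

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            classify_course(-1)


class TestCardinalSigns:
    def test_all_five_present(self):
        profile = make_profile(
            duration_days=14,
            discoloured_discharge=True,
            severe_local_pain=True,
            fever_celsius=39.0,
            inflammatory_markers_elevated="yes",
            two_stage_course=True,
        )
        assert count_abrs_signs(profile) == 5

    def test_all_absent(self):
        assert count_abrs_signs(make_profile(duration_days=14)) == 0

    def test_three_signs_counted_directly(self):
        profile = make_profile(
            duration_days=14,
            discoloured_discharge=True,
            fever_celsius=38.6,
            inflammatory_markers_elevated="yes",
        )
        assert count_abrs_signs(profile) == 3

    def test_fever_exactly_38_does_not_count(self):
        """The fever sign requires strictly more than 38 degC."""
        assert count_abrs_signs(make_profile(duration_days=14, fever_celsius=38.0)) == 0
        assert count_abrs_signs(make_profile(duration_days=14, fever_celsius=38.1)) == 1

    def test_unknown_markers_do_not_count(self):
        for value in ("no", "unknown"):
            assert (
                count_abrs_signs(
                    make_profile(duration_days=14, inflammatory_markers_elevated=value)
                )
                == 0
            )


class TestTemporalCriterion:
    @pytest.mark.parametrize(
        "days,worsening,expected",
        [
            (11, False, True),  # lasting more than 10 days
            (10, False, False),  # strictly more than 10
            (7, True, True),  # worsening after day 5
            (5, False, False),
        ],
    )
    def test_boundaries(self, days, worsening, expected):
        profile = make_profile(duration_days=days, worsening_after_day5=worsening)
        assert meets_abrs_temporal_criterion(profile) is expected


ABX_SIGNS = dict(
    discoloured_discharge=True,
    severe_local_pain=True,
    fever_celsius=38.6,
    inflammatory_markers_elevated="yes",
)


class TestInfer:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(duration_days=5), DiagnosisCategory.COMMON_COLD),
            (
                dict(duration_days=14, discoloured_discharge=True, two_stage_course=True),
                DiagnosisCategory.POST_VIRAL_ARS,
            ),
            (dict(duration_days=14, **ABX_SIGNS), DiagnosisCategory.ABRS),
            (dict(duration_days=120), DiagnosisCategory.CRS),
            (
                dict(
                    duration_days=120,
                    nasal_polyps="no",
                    serum_ige_low="yes",
                    refractory_to_incs=True,
                ),
                DiagnosisCategory.CRS_MACROLIDE_ELIGIBLE,
            ),
            (
                dict(duration_days=120, postop_purulent_complication=True),
                DiagnosisCategory.CRS_COMPLICATION,
            ),
            # complication outranks macrolide eligibility
            (
                dict(
                    duration_days=120,
                    postop_purulent_complication=True,
                    nasal_polyps="no",
                    serum_ige_low="yes",
                    refractory_to_incs=True,
                ),
                DiagnosisCategory.CRS_COMPLICATION,
            ),
            # chronic signs never make an acute bacterial diagnosis
            (dict(duration_days=84, **ABX_SIGNS), DiagnosisCategory.CRS),
        ],
    )
    def test_categories(self, epos, kwargs, expected):
        diagnosis = infer(make_profile(**kwargs), epos)
        assert diagnosis.category is expected
        assert diagnosis.fired_rules  # provenance always recorded

    def test_exhaustive_oracle_equivalence(self, epos):
        """Engine output equals an independently coded flat conditional over
        the full grid of boundary durations, worsening flags, sign
        combinations, and chronic modifiers."""
        n = 0
        for kwargs in profile_grid():
            profile = make_profile(**kwargs)
            oracle_kwargs = {k: v for k, v in kwargs.items() if k != "patient_id"}
            assert infer(profile, epos).category.value == flat_classify(**oracle_kwargs), kwargs
            n += 1
        assert n > 30000  # the grid is genuinely exhaustive, not truncated

    @settings(max_examples=200, derandomize=True)
    @given(
        duration=st.integers(11, 83),
        base_signs=st.sets(st.sampled_from(["discharge", "pain", "fever", "markers"]), min_size=3),
    )
    def test_adding_a_sign_never_revokes_abrs(self, epos, duration, base_signs):
        """Monotonicity: once an acute presentation meets the bacterial
        criterion, adding the remaining cardinal sign cannot weaken it."""
        kwargs = dict(duration_days=duration)
        if "discharge" in base_signs:
            kwargs["discoloured_discharge"] = True
        if "pain" in base_signs:
            kwargs["severe_local_pain"] = True
        if "fever" in base_signs:
            kwargs["fever_celsius"] = 39.0
        if "markers" in base_signs:
            kwargs["inflammatory_markers_elevated"] = "yes"
        assert infer(make_profile(**kwargs), epos).category is DiagnosisCategory.ABRS
        kwargs["two_stage_course"] = True
        assert infer(make_profile(**kwargs), epos).category is DiagnosisCategory.ABRS


class TestForwardChainer:
    def test_empty_ruleset_derives_only_predicates(self):
        ruleset = RuleSet(rules=(), facts=frozenset())
        facts, fired = fire_rules(make_profile(duration_days=5), ruleset)
        assert fired == ()
        assert "course_acute" in facts and "dx_common_cold" not in facts

    def test_two_step_chain(self):
        ruleset = RuleSet(
            rules=(
                Rule("r1", ("course_acute",), "B", priority=1),
                Rule("r2", ("B",), "C", priority=2),
            ),
            facts=frozenset({"B", "C"}),
        )
        facts, fired = fire_rules(make_profile(duration_days=5), ruleset)
        assert {"B", "C"} <= facts
        assert fired == ("r1", "r2")

    def test_chain_fires_even_when_rule_order_is_reversed(self):
        """A rule listed before its enabling rule still fires at the fixpoint."""
        ruleset = RuleSet(
            rules=(
                Rule("late", ("B",), "C", priority=1),
                Rule("early", ("course_acute",), "B", priority=2),
            ),
            facts=frozenset({"B", "C"}),
        )
        facts, fired = fire_rules(make_profile(duration_days=5), ruleset)
        assert {"B", "C"} <= facts
        assert fired == ("late", "early")  # log sorted by (priority, rule_id)

    def test_fixpoint_is_order_independent(self, epos):
        """Permuting rule order changes neither the fact set nor the log."""
        profiles = [
            make_profile(duration_days=14, **ABX_SIGNS),
            make_profile(duration_days=120, postop_purulent_complication=True),
            make_profile(duration_days=5),
        ]
        rng = random.Random(7)
        for profile in profiles:
            reference = fire_rules(profile, epos)
            for _ in range(10):
                shuffled = list(epos.rules)
                rng.shuffle(shuffled)
                permuted = RuleSet(rules=tuple(shuffled), facts=epos.facts)
                assert fire_rules(profile, permuted) == reference

    def test_undeclared_antecedent_rejected(self):
        with pytest.raises(ConfigurationError, match="undeclared|neither"):
            RuleSet(rules=(Rule("r", ("no_such_token",), "B"),), facts=frozenset({"B"}))

    def test_undeclared_consequent_rejected(self):
        with pytest.raises(ConfigurationError, match="not a declared fact"):
            RuleSet(rules=(Rule("r", ("course_acute",), "mystery"),), facts=frozenset())

    def test_duplicate_rule_id_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            RuleSet(
                rules=(
                    Rule("r", ("course_acute",), "B"),
                    Rule("r", ("course_chronic",), "B"),
                ),
                facts=frozenset({"B"}),
            )


def test_ruleset_yaml_round_trip(tmp_path, epos):
    """A rule set written to YAML and reloaded infers identically."""
    import yaml

    payload = {
        "facts": sorted(epos.facts),
        "rules": [
            {"id": r.rule_id, "priority": r.priority, "if": list(r.antecedent), "then": r.consequent}
            for r in epos.rules
        ],
    }
    path = tmp_path / "rules.yaml"
    path.write_text(yaml.safe_dump(payload))
    from rhinoguide.rule_engine import load_ruleset

    reloaded = load_ruleset(path)
    profile = make_profile(duration_days=14, **ABX_SIGNS)
    assert infer(profile, reloaded) == infer(profile, epos)
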