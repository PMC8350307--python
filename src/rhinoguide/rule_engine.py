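"""Forward-chaining inference over declarative if-then rules.

The engine is generic: a :class:`RuleSet` is a list of rules whose
antecedents are conjunctions of named predicates (evaluated on the patient
profile) and previously derived facts, and whose consequent is a single fact
token. Facts are only ever added, never retracted, so chaining reaches a
unique monotone fixpoint regardless of rule order.

The shipped default rule set encodes the EPOS 2012 criteria:

* a course shorter than 12 weeks (84 days) is acute, 84 days or more is
  chronic;
* antibiotic treatment of acute disease is considered when symptoms last
  more than 10 days or worsen after day 5 *and* at least 3 of 5 cardinal
  signs are present (discoloured/purulent discharge, severe local pain,
  fever above 38 °C, raised ESR/CRP, two-stage course);
* in chronic disease a macrolide trial is reserved for refractory,
  polyp-free patients with low total IgE, and a postoperative purulent
  complication is an antibiotic indication in its own right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import yaml

from .patient_model import (
    Diagnosis,
    DiagnosisCategory,
    SymptomProfile,
    TriState,
)

__all__ = [
    "Course",
    "Rule",
    "RuleSet",
    "ConfigurationError",
    "PREDICATES",
    "CHRONIC_THRESHOLD_DAYS",
    "FEVER_THRESHOLD_CELSIUS",
    "classify_course",
    "count_abrs_signs",
    "meets_abrs_temporal_criterion",
    "fire_rules",
    "infer",
    "load_ruleset",
    "default_ruleset",
]

#: Symptom duration (days) at which the course is classified chronic.
#: "Less than 12 weeks" is acute, so exactly 84 days falls on the chronic side.
CHRONIC_THRESHOLD_DAYS = 84

#: Fever counts as a cardinal sign strictly above this temperature.
FEVER_THRESHOLD_CELSIUS = 38.0


class Course(str, Enum):
    ACUTE = "ACUTE"
    CHRONIC = "CHRONIC"


class ConfigurationError(ValueError):
    """A rule set references undeclared facts/predicates or repeats a rule id."""


def classify_course(duration_days: int) -> Course:
    """Acute (< 84 days) versus chronic (>= 84 days) disease course."""
    if duration_days < 0:
        raise ValueError(f"duration_days must be non-negative, got {duration_days}")
    return Course.ACUTE if duration_days < CHRONIC_THRESHOLD_DAYS else Course.CHRONIC


def count_abrs_signs(profile: SymptomProfile) -> int:
    """Number of the five cardinal bacterial signs present (0-5).

    Unknown tri-state findings count as absent; fever counts only when
    strictly above 38.0 °C.
    """
    return sum(
        (
            profile.discoloured_discharge,
            profile.severe_local_pain,
            profile.fever_celsius is not None
            and profile.fever_celsius > FEVER_THRESHOLD_CELSIUS,
            profile.inflammatory_markers_elevated is TriState.YES,
            profile.two_stage_course,
        )
    )


def meets_abrs_temporal_criterion(profile: SymptomProfile) -> bool:
    """Symptoms lasting more than 10 days, or worsening after day 5."""
    return profile.duration_days > 10 or profile.worsening_after_day5


#: Built-in predicate vocabulary available to rule antecedents.
PREDICATES: Mapping[str, Callable[[SymptomProfile], bool]] = {
    "course_acute": lambda p: classify_course(p.duration_days) is Course.ACUTE,
    "course_chronic": lambda p: classify_course(p.duration_days) is Course.CHRONIC,
    "temporal_criterion": meets_abrs_temporal_criterion,
    "signs_ge_3": lambda p: count_abrs_signs(p) >= 3,
    "polyps_absent": lambda p: p.nasal_polyps is TriState.NO,
    "ige_low": lambda p: p.serum_ige_low is TriState.YES,
    "refractory_incs": lambda p: p.refractory_to_incs,
    "postop_complication": lambda p: p.postop_purulent_complication,
}


@dataclass(frozen=True)
class Rule:
    """One if-then rule: fire when every antecedent token holds."""

    rule_id: str
    antecedent: tuple[str, ...]
    consequent: str
    priority: int = 100

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.priority, self.rule_id)


@dataclass(frozen=True)
class RuleSet:
    """An ordered rule collection plus its declared fact vocabulary."""

    rules: tuple[Rule, ...]
    facts: frozenset[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self.rules:
            if rule.rule_id in seen:
                raise ConfigurationError(f"duplicate rule id {rule.rule_id!r}")
            seen.add(rule.rule_id)
            for token in rule.antecedent:
                if token not in self.facts and token not in PREDICATES:
                    raise ConfigurationError(
                        f"rule {rule.rule_id!r}: antecedent {token!r} is neither a "
                        f"declared fact nor a built-in predicate"
                    )
            if rule.consequent not in self.facts:
                raise ConfigurationError(
                    f"rule {rule.rule_id!r}: consequent {rule.consequent!r} is not a "
                    f"declared fact"
                )


def fire_rules(
    profile: SymptomProfile, ruleset: RuleSet
) -> tuple[frozenset[str], tuple[str, ...]]:
    """Run forward chaining to the fixpoint.

    Returns the derived fact set (seeded with every built-in predicate that
    holds for the profile) and the fired-rule log sorted by
    ``(priority, rule_id)``. Because facts grow monotonically the fixpoint is
    unique and independent of rule order.
    """
    facts: set[str] = {name for name, holds in PREDICATES.items() if holds(profile)}
    fired: list[Rule] = []
    ordered = sorted(ruleset.rules, key=lambda r: r.sort_key)
    changed = True
    while changed:
        changed = False
        for rule in ordered:
            if rule.consequent in facts:
                continue
            if all(token in facts for token in rule.antecedent):
                facts.add(rule.consequent)
                fired.append(rule)
                changed = True
    fired.sort(key=lambda r: r.sort_key)
    return frozenset(facts), tuple(rule.rule_id for rule in fired)


#: Diagnosis facts in descending clinical precedence. The chainer derives
#: every consistent diagnosis (a bacterial acute case also satisfies the
#: post-viral and common-cold antecedents); the strongest one wins.
_DIAGNOSIS_PRECEDENCE: tuple[tuple[str, DiagnosisCategory], ...] = (
    ("dx_crs_complication", DiagnosisCategory.CRS_COMPLICATION),
    ("dx_crs_macrolide", DiagnosisCategory.CRS_MACROLIDE_ELIGIBLE),
    ("dx_crs", DiagnosisCategory.CRS),
    ("dx_abrs", DiagnosisCategory.ABRS),
    ("dx_post_viral", DiagnosisCategory.POST_VIRAL_ARS),
    ("dx_common_cold", DiagnosisCategory.COMMON_COLD),
)


def infer(profile: SymptomProfile, ruleset: Optional[RuleSet] = None) -> Diagnosis:
    """Classify a profile into exactly one diagnostic category.

    Runs the forward chainer and resolves the derived diagnosis facts by
    precedence: complication > macrolide-eligible > chronic baseline on the
    chronic branch; bacterial > post-viral > common cold on the acute branch.
    """
    if ruleset is None:
        ruleset = default_ruleset()
    facts, fired = fire_rules(profile, ruleset)
    for token, category in _DIAGNOSIS_PRECEDENCE:
        if token in facts:
            return Diagnosis(category=category, fired_rules=fired)
    raise ConfigurationError(
        f"rule set derived no diagnosis for patient {profile.patient_id!r}; "
        f"the knowledge base does not cover this presentation"
    )


# ---------------------------------------------------------------------------
# rule set loading


def _parse_ruleset(payload: Mapping) -> RuleSet:
    if not isinstance(payload, Mapping):
        raise ConfigurationError("rule set file must be a mapping")
    try:
        fact_list = payload["facts"]
        rule_list = payload["rules"]
    except KeyError as exc:
        raise ConfigurationError(f"rule set file lacks top-level key {exc}") from None
    rules = []
    for entry in rule_list:
        try:
            rules.append(
                Rule(
                    rule_id=str(entry["id"]),
                    antecedent=tuple(str(t) for t in entry["if"]),
                    consequent=str(entry["then"]),
                    priority=int(entry.get("priority", 100)),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed rule entry {entry!r}: {exc}") from None
    return RuleSet(rules=tuple(rules), facts=frozenset(str(f) for f in fact_list))


def load_ruleset(path: str | Path) -> RuleSet:
    """Load a declarative YAML/JSON rule set file."""
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    return _parse_ruleset(payload)


_DEFAULT_RULESET: Optional[RuleSet] = None


def default_ruleset() -> RuleSet:
    """The shipped EPOS 2012 knowledge base (cached)."""
    global _DEFAULT_RULESET
    if _DEFAULT_RULESET is None:
        text = resources.files("rhinoguide.rulesets").joinpath("epos2012.yaml").read_text()
        _DEFAULT_RULESET = _parse_ruleset(yaml.safe_load(text))
    return _DEFAULT_RULESET
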