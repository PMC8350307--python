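import itertools

import pytest

from rhinoguide.patient_model import SymptomProfile
from rhinoguide.rule_engine import default_ruleset


@pytest.fixture(scope="session")
def epos():
    """The shipped EPOS 2012 rule set."""
    return default_ruleset()


def make_profile(**kwargs) -> SymptomProfile:
    kwargs.setdefault("patient_id", "t")
    kwargs.setdefault("duration_days", 5)
    return SymptomProfile(**kwargs)


def profile_grid():
    """Every valid profile over boundary durations x worsening x sign
    combinations x chronic-modifier combinations.

    Invalid combinations (worsening with duration < 6) are skipped; the
    unilateral-predominance flags are held false since they do not enter
    any rule.
    """
    durations = (0, 5, 6, 10, 11, 83, 84, 85)
    fevers = (None, 38.0, 38.6)
    tristates = ("yes", "no", "unknown")
    for (
        duration,
        worsening,
        discharge,
        pain,
        fever,
        markers,
        two_stage,
        polyps,
        ige,
        refractory,
        postop,
    ) in itertools.product(
        durations,
        (False, True),
        (False, True),
        (False, True),
        fevers,
        tristates,
        (False, True),
        tristates,
        tristates,
        (False, True),
        (False, True),
    ):
        if worsening and duration < 6:
            continue
        yield dict(
            patient_id="grid",
            duration_days=duration,
            worsening_after_day5=worsening,
            discoloured_discharge=discharge,
            severe_local_pain=pain,
            fever_celsius=fever,
            inflammatory_markers_elevated=markers,
            two_stage_course=two_stage,
            nasal_polyps=polyps,
            serum_ige_low=ige,
            refractory_to_incs=refractory,
            postop_purulent_complication=postop,
        )
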