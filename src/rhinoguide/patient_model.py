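"""Domain types for rhinosinusitis presentations and engine outputs.

A :class:`SymptomProfile` captures one patient presentation in terms of the
clinical features the EPOS guideline reasons over: how long symptoms have
lasted, whether the course worsened after day 5 (double-sickening), the five
cardinal signs of bacterial superinfection, and the chronic-disease modifiers
(nasal polyps, total IgE, refractoriness to intranasal corticosteroid,
postoperative purulent complication).

Tri-state clinical findings (``yes`` / ``no`` / ``unknown``) are modelled
explicitly: an ``unknown`` never satisfies a sign predicate, so missing
laboratory data cannot inflate an antibiotic indication.
"""

from __future__ import annotations

import csv
import json
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError, model_validator

__all__ = [
    "TriState",
    "DiagnosisCategory",
    "Therapy",
    "SymptomProfile",
    "Diagnosis",
    "TreatmentPlan",
    "SchemaError",
    "ProfileValidationError",
    "validate_profile",
    "profile_to_record",
    "read_profiles_csv",
    "read_profiles_json",
    "write_profiles_csv",
    "PROFILE_CSV_COLUMNS",
]


class TriState(str, Enum):
    """Three-valued clinical finding; ``unknown`` counts as absent in all rules."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class DiagnosisCategory(str, Enum):
    """Mutually exclusive diagnostic categories of the decision algorithm."""

    COMMON_COLD = "COMMON_COLD"
    POST_VIRAL_ARS = "POST_VIRAL_ARS"
    ABRS = "ABRS"
    CRS = "CRS"
    CRS_MACROLIDE_ELIGIBLE = "CRS_MACROLIDE_ELIGIBLE"
    CRS_COMPLICATION = "CRS_COMPLICATION"


#: Categories on the acute (< 12 week) branch of the algorithm.
ACUTE_CATEGORIES = frozenset(
    {DiagnosisCategory.COMMON_COLD, DiagnosisCategory.POST_VIRAL_ARS, DiagnosisCategory.ABRS}
)

#: Categories on the chronic branch.
CHRONIC_CATEGORIES = frozenset(
    {
        DiagnosisCategory.CRS,
        DiagnosisCategory.CRS_MACROLIDE_ELIGIBLE,
        DiagnosisCategory.CRS_COMPLICATION,
    }
)


class Therapy(str, Enum):
    """Therapy classes recommended by the decision support system."""

    DECONGESTANT = "DECONGESTANT"
    DECONGESTANT_PLUS_INCS = "DECONGESTANT_PLUS_INCS"
    ANTIBIOTIC = "ANTIBIOTIC"
    INCS = "INCS"
    MACROLIDE_TRIAL = "MACROLIDE_TRIAL"


class SchemaError(ValueError):
    """A raw record is structurally unusable (missing or unparseable field)."""


class ProfileValidationError(ValueError):
    """A record parses but violates a clinical invariant."""


class SymptomProfile(BaseModel):
    """One validated patient presentation.

    Unilateral-predominance flags are recorded for completeness but the
    cardinal signs are satisfied by the discharge/pain booleans alone; the
    guideline lists predominance parenthetically, not as a separate sign.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    patient_id: str
    duration_days: int = Field(ge=0, description="days since symptom onset")
    worsening_after_day5: bool = False
    discoloured_discharge: bool = False
    discharge_unilateral: bool = False
    severe_local_pain: bool = False
    pain_unilateral: bool = False
    fever_celsius: Optional[float] = Field(default=None, ge=34.0, le=43.0)
    inflammatory_markers_elevated: TriState = TriState.UNKNOWN
    two_stage_course: bool = False
    nasal_polyps: TriState = TriState.UNKNOWN
    serum_ige_low: TriState = TriState.UNKNOWN
    refractory_to_incs: bool = False
    postop_purulent_complication: bool = False
    specialist_override_antibiotic: bool = False

    @model_validator(mode="after")
    def _clinical_invariants(self) -> "SymptomProfile":
        if self.worsening_after_day5 and self.duration_days < 6:
            raise ValueError(
                "worsening_after_day5 requires duration_days >= 6: "
                "symptoms cannot worsen after day 5 of an illness shorter than 6 days"
            )
        if self.discharge_unilateral and not self.discoloured_discharge:
            raise ValueError(
                "discharge_unilateral requires discoloured_discharge: "
                "one-sided predominance presupposes discoloured secretion"
            )
        if self.pain_unilateral and not self.severe_local_pain:
            raise ValueError(
                "pain_unilateral requires severe_local_pain: "
                "one-sided predominance presupposes severe local pain"
            )
        return self


class Diagnosis(BaseModel):
    """Engine output: exactly one category plus the rules that produced it."""

    model_config = ConfigDict(frozen=True)

    category: DiagnosisCategory
    fired_rules: tuple[str, ...]

    @model_validator(mode="after")
    def _nonempty_provenance(self) -> "Diagnosis":
        if not self.fired_rules:
            raise ValueError("a diagnosis must cite at least one fired rule")
        return self


class TreatmentPlan(BaseModel):
    """Recommended therapy class; ``antibiotic_indicated`` flags any systemic antibiotic."""

    model_config = ConfigDict(frozen=True)

    therapy: Therapy
    antibiotic_indicated: bool

    @model_validator(mode="after")
    def _flag_consistent(self) -> "TreatmentPlan":
        expected = self.therapy in (Therapy.ANTIBIOTIC, Therapy.MACROLIDE_TRIAL)
        if self.antibiotic_indicated != expected:
            raise ValueError(
                f"antibiotic_indicated must be {expected} for therapy {self.therapy.value}"
            )
        return self


# ---------------------------------------------------------------------------
# record <-> profile conversion

_BOOL_FIELDS = (
    "worsening_after_day5",
    "discoloured_discharge",
    "discharge_unilateral",
    "severe_local_pain",
    "pain_unilateral",
    "two_stage_course",
    "refractory_to_incs",
    "postop_purulent_complication",
    "specialist_override_antibiotic",
)
_TRISTATE_FIELDS = ("inflammatory_markers_elevated", "nasal_polyps", "serum_ige_low")

PROFILE_CSV_COLUMNS = (
    "patient_id",
    "duration_days",
    "worsening_after_day5",
    "discoloured_discharge",
    "discharge_unilateral",
    "severe_local_pain",
    "pain_unilateral",
    "fever_celsius",
    "inflammatory_markers_elevated",
    "two_stage_course",
    "nasal_polyps",
    "serum_ige_low",
    "refractory_to_incs",
    "postop_purulent_complication",
    "specialist_override_antibiotic",
)


def _parse_bool(value: Any, field: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in ("true", "1"):
            return True
        if lowered in ("false", "0", ""):
            return False
    raise SchemaError(f"field {field!r}: cannot interpret {value!r} as a boolean")


def _parse_tristate(value: Any, field: str) -> TriState:
    if isinstance(value, TriState):
        return value
    if value is None:
        return TriState.UNKNOWN
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered == "":
            return TriState.UNKNOWN
        try:
            return TriState(lowered)
        except ValueError:
            pass
    raise SchemaError(f"field {field!r}: expected yes/no/unknown, got {value!r}")


def validate_profile(record: Mapping[str, Any]) -> SymptomProfile:
    """Validate a raw field mapping into a :class:`SymptomProfile`.

    Absent optional fields default to false/unknown. Raises
    :class:`SchemaError` when a required field is missing or unparseable and
    :class:`ProfileValidationError` when a clinical invariant is violated.
    Validating the dump of an already-valid profile returns an equal profile.
    """
    if isinstance(record, SymptomProfile):
        return record
    data: dict[str, Any] = {}
    patient_id = record.get("patient_id", record.get("id"))
    if patient_id is None or str(patient_id) == "":
        raise SchemaError("field 'patient_id': required but missing")
    data["patient_id"] = str(patient_id)

    raw_duration = record.get("duration_days")
    if raw_duration is None or raw_duration == "":
        raise SchemaError("field 'duration_days': required but missing")
    try:
        duration = int(raw_duration)
    except (TypeError, ValueError):
        raise SchemaError(
            f"field 'duration_days': cannot interpret {raw_duration!r} as an integer"
        ) from None
    data["duration_days"] = duration

    fever = record.get("fever_celsius")
    if fever is None or fever == "":
        data["fever_celsius"] = None
    else:
        try:
            data["fever_celsius"] = float(fever)
        except (TypeError, ValueError):
            raise SchemaError(
                f"field 'fever_celsius': cannot interpret {fever!r} as a temperature"
            ) from None

    for field in _BOOL_FIELDS:
        if field in record and record[field] is not None:
            data[field] = _parse_bool(record[field], field)
    for field in _TRISTATE_FIELDS:
        if field in record:
            data[field] = _parse_tristate(record[field], field)

    known = set(PROFILE_CSV_COLUMNS) | {"id"}
    unknown = set(record) - known
    if unknown:
        raise SchemaError(f"unrecognised fields: {sorted(unknown)}")

    try:
        return SymptomProfile(**data)
    except PydanticValidationError as exc:
        raise ProfileValidationError(str(exc)) from exc


def profile_to_record(profile: SymptomProfile) -> dict[str, str]:
    """Serialise a profile to the flat string record of the CSV schema."""
    record: dict[str, str] = {}
    for field in PROFILE_CSV_COLUMNS:
        value = getattr(profile, field)
        if field == "fever_celsius":
            record[field] = "" if value is None else format(value, "g")
        elif isinstance(value, bool):
            record[field] = "true" if value else "false"
        elif isinstance(value, TriState):
            record[field] = value.value
        else:
            record[field] = str(value)
    return record


def read_profiles_csv(path: str | Path) -> Iterator[tuple[int, SymptomProfile]]:
    """Yield ``(line_number, profile)`` from a patient CSV; raises on bad header."""
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = {"patient_id", "duration_days"} - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: header lacks required columns {sorted(missing)}")
        for row in reader:
            yield reader.line_num, validate_profile(row)


def read_profiles_json(path: str | Path) -> Iterator[tuple[int, SymptomProfile]]:
    """Yield ``(index, profile)`` from a JSON array of patient objects."""
    with open(path) as handle:
        payload = json.load(handle)
    if not isinstance(payload, list):
        raise SchemaError(f"{path}: expected a JSON array of patient objects")
    for index, record in enumerate(payload):
        yield index, validate_profile(record)


def write_profiles_csv(path: str | Path, profiles: Iterable[SymptomProfile]) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=list(PROFILE_CSV_COLUMNS))
        writer.writeheader()
        for profile in profiles:
            writer.writerow(profile_to_record(profile))
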