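"""Concordance and treatment-distribution statistics for evaluated cohorts.

The evaluator classifies every cohort record with the rule engine, maps the
diagnosis to a therapy, and compares that therapy against the reference
(specialist) label. Proportions are kept as exact rationals internally and
rounded half-up only for display, matching how the study's percentages are
printed: one decimal within the acute and chronic blocks, two decimals for
the overall antibiotic fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import pandas as pd

from .patient_model import (
    ACUTE_CATEGORIES,
    Diagnosis,
    DiagnosisCategory,
    Therapy,
)
from .cohort_synth import CohortRecord
from .recommender import recommend
from .rule_engine import RuleSet, infer

__all__ = [
    "ConcordanceResult",
    "TherapyBlock",
    "EvaluationReport",
    "round_half_up",
    "percentage",
    "concordance",
    "distribution_table",
    "evaluate_cohort",
]


def round_half_up(value: Fraction | float, ndigits: int) -> float:
    """Round with ties away from zero, as the study's printed tables do."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Exact-rational percentage rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ValueError("percentage undefined for an empty denominator")
    return round_half_up(Fraction(numerator * 100, denominator), ndigits)


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between engine and reference labels."""

    n_total: int
    n_agree: int

    @property
    def proportion(self) -> Fraction:
        return Fraction(self.n_agree, self.n_total)

    @property
    def pct(self) -> float:
        return percentage(self.n_agree, self.n_total, 1)


def concordance(
    engine_labels: Sequence[str | Therapy], reference_labels: Sequence[str | Therapy]
) -> ConcordanceResult:
    """Fraction of positions where engine and reference labels agree."""
    if len(engine_labels) != len(reference_labels):
        raise ValueError(
            f"label lists differ in length: {len(engine_labels)} vs {len(reference_labels)}"
        )
    if not engine_labels:
        raise ValueError("concordance is undefined on empty label lists")
    n_agree = sum(
        str(getattr(e, "value", e)) == str(getattr(r, "value", r))
        for e, r in zip(engine_labels, reference_labels)
    )
    return ConcordanceResult(n_total=len(engine_labels), n_agree=n_agree)


@dataclass(frozen=True)
class TherapyBlock:
    """Per-therapy counts and percentages within one sub-cohort."""

    n: int
    counts: Mapping[str, int]
    percentages: Mapping[str, float]
    antibiotic_indicated_count: int
    antibiotic_indicated_pct: float


@dataclass(frozen=True)
class EvaluationReport:
    """Full evaluation output: concordance, therapy distributions, confusion."""

    n_total: int
    n_agree: int
    concordance_pct: float
    ars: TherapyBlock
    crs: TherapyBlock
    overall_antibiotic_count: int
    overall_antibiotic_pct: float
    confusion: pd.DataFrame  # reference label (rows) x engine label (columns)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_agree": self.n_agree,
            "concordance_pct": self.concordance_pct,
            "ars": {
                "n": self.ars.n,
                "counts": dict(self.ars.counts),
                "percentages": dict(self.ars.percentages),
                "antibiotic_indicated_count": self.ars.antibiotic_indicated_count,
                "antibiotic_indicated_pct": self.ars.antibiotic_indicated_pct,
            },
            "crs": {
                "n": self.crs.n,
                "counts": dict(self.crs.counts),
                "percentages": dict(self.crs.percentages),
                "antibiotic_indicated_count": self.crs.antibiotic_indicated_count,
                "antibiotic_indicated_pct": self.crs.antibiotic_indicated_pct,
            },
            "overall_antibiotic_count": self.overall_antibiotic_count,
            "overall_antibiotic_pct": self.overall_antibiotic_pct,
            "confusion": {
                ref: {eng: int(v) for eng, v in row.items()}
                for ref, row in self.confusion.to_dict(orient="index").items()
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        """Human-readable table in the style of the study's results section."""
        lines = ["block\ttherapy\tcount\tpercent"]
        for name, block in (("ARS", self.ars), ("CRS", self.crs)):
            for therapy, count in block.counts.items():
                lines.append(f"{name}\t{therapy}\t{count}\t{block.percentages[therapy]}")
            lines.append(
                f"{name}\tantibiotic_indicated\t{block.antibiotic_indicated_count}"
                f"\t{block.antibiotic_indicated_pct}"
            )
        lines.append(
            f"overall\tantibiotic_indicated\t{self.overall_antibiotic_count}"
            f"\t{self.overall_antibiotic_pct}"
        )
        lines.append(f"overall\tconcordance\t{self.n_agree}/{self.n_total}\t{self.concordance_pct}")
        return "\n".join(lines)


def _therapy_block(plans: Sequence, ndigits: int = 1) -> TherapyBlock:
    n = len(plans)
    counts: dict[str, int] = {}
    n_abx = 0
    for plan in plans:
        counts[plan.therapy.value] = counts.get(plan.therapy.value, 0) + 1
        n_abx += plan.antibiotic_indicated
    percentages = {t: percentage(c, n, ndigits) for t, c in counts.items()}
    return TherapyBlock(
        n=n,
        counts=counts,
        percentages=percentages,
        antibiotic_indicated_count=n_abx,
        antibiotic_indicated_pct=percentage(n_abx, n, ndigits) if n else 0.0,
    )


def distribution_table(
    diagnoses: Sequence[Diagnosis], plans: Sequence
) -> tuple[TherapyBlock, TherapyBlock, int, float]:
    """Therapy distributions within the acute and chronic sub-cohorts.

    Returns (ARS block, CRS block, overall antibiotic count, overall
    antibiotic percentage at two decimals). Antibiotic pooling counts
    ``antibiotic_indicated`` therapies (plain antibiotic and macrolide
    trial together), as the study's chronic block does.
    """
    if len(diagnoses) != len(plans):
        raise ValueError("diagnoses and plans must be aligned")
    ars_plans = [p for d, p in zip(diagnoses, plans) if d.category in ACUTE_CATEGORIES]
    crs_plans = [p for d, p in zip(diagnoses, plans) if d.category not in ACUTE_CATEGORIES]
    ars = _therapy_block(ars_plans)
    crs = _therapy_block(crs_plans)
    n_abx = ars.antibiotic_indicated_count + crs.antibiotic_indicated_count
    overall_pct = percentage(n_abx, len(diagnoses), 2) if diagnoses else 0.0
    return ars, crs, n_abx, overall_pct


def evaluate_cohort(
    records: Sequence[CohortRecord], ruleset: Optional[RuleSet] = None
) -> EvaluationReport:
    """Classify every record and compare against its reference label."""
    if not records:
        raise ValueError("cannot evaluate an empty cohort")
    diagnoses = [infer(rec.profile, ruleset) for rec in records]
    plans = [recommend(d) for d in diagnoses]
    engine_labels = [p.therapy.value for p in plans]
    reference_labels = [rec.reference_label.value for rec in records]
    agree = concordance(engine_labels, reference_labels)
    ars, crs, n_abx, overall_pct = distribution_table(diagnoses, plans)
    confusion = pd.crosstab(
        pd.Series(reference_labels, name="reference"),
        pd.Series(engine_labels, name="engine"),
    )
    return EvaluationReport(
        n_total=agree.n_total,
        n_agree=agree.n_agree,
        concordance_pct=agree.pct,
        ars=ars,
        crs=crs,
        overall_antibiotic_count=n_abx,
        overall_antibiotic_pct=overall_pct,
        confusion=confusion,
    )
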