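"""Map each diagnostic category to its guideline therapy class.

The mapping is total on the six categories. Only three categories carry a
systemic antibiotic indication: acute bacterial rhinosinusitis, chronic
disease with a postoperative purulent complication (both plain antibiotics),
and the macrolide trial in refractory polyp-free chronic disease with low
total IgE. No drug names, doses or durations are modelled — the system
recommends therapy classes only.
"""

from __future__ import annotations

from .patient_model import Diagnosis, DiagnosisCategory, Therapy, TreatmentPlan

__all__ = ["THERAPY_BY_CATEGORY", "ANTIBIOTIC_INDICATED_CATEGORIES", "recommend"]

THERAPY_BY_CATEGORY: dict[DiagnosisCategory, Therapy] = {
    DiagnosisCategory.COMMON_COLD: Therapy.DECONGESTANT,
    DiagnosisCategory.POST_VIRAL_ARS: Therapy.DECONGESTANT_PLUS_INCS,
    DiagnosisCategory.ABRS: Therapy.ANTIBIOTIC,
    DiagnosisCategory.CRS: Therapy.INCS,
    DiagnosisCategory.CRS_MACROLIDE_ELIGIBLE: Therapy.MACROLIDE_TRIAL,
    DiagnosisCategory.CRS_COMPLICATION: Therapy.ANTIBIOTIC,
}

ANTIBIOTIC_INDICATED_CATEGORIES = frozenset(
    {
        DiagnosisCategory.ABRS,
        DiagnosisCategory.CRS_COMPLICATION,
        DiagnosisCategory.CRS_MACROLIDE_ELIGIBLE,
    }
)


def recommend(diagnosis: Diagnosis | DiagnosisCategory) -> TreatmentPlan:
    """Return the therapy class for a diagnosis.

    Accepts either a full :class:`Diagnosis` or a bare category.
    """
    category = diagnosis.category if isinstance(diagnosis, Diagnosis) else diagnosis
    try:
        therapy = THERAPY_BY_CATEGORY[category]
    except KeyError:
        raise ValueError(f"no therapy mapping for category {category!r}") from None
    return TreatmentPlan(
        therapy=therapy,
        antibiotic_indicated=therapy in (Therapy.ANTIBIOTIC, Therapy.MACROLIDE_TRIAL),
    )
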