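"""Independent brute-force classifier used only as a test oracle.

A single flat conditional over the raw fields, written without reference to
the rule engine: duration >= 84 days is chronic; a postoperative purulent
complication dominates the chronic branch, then the macrolide triple
(refractory + no polyps + low IgE), then baseline chronic disease. On the
acute branch, the temporal criterion (> 10 days or worsening after day 5)
plus at least 3 of 5 cardinal signs means bacterial disease; the temporal
criterion alone means post-viral disease; otherwise a common cold.
"""


def flat_classify(
    duration_days: int,
    worsening_after_day5: bool = False,
    discoloured_discharge: bool = False,
    severe_local_pain: bool = False,
    fever_celsius: float | None = None,
    inflammatory_markers_elevated: str = "unknown",
    two_stage_course: bool = False,
    nasal_polyps: str = "unknown",
    serum_ige_low: str = "unknown",
    refractory_to_incs: bool = False,
    postop_purulent_complication: bool = False,
) -> str:
    if duration_days >= 84:
        if postop_purulent_complication:
            return "CRS_COMPLICATION"
        if refractory_to_incs and nasal_polyps == "no" and serum_ige_low == "yes":
            return "CRS_MACROLIDE_ELIGIBLE"
        return "CRS"
    n_signs = (
        int(discoloured_discharge)
        + int(severe_local_pain)
        + int(fever_celsius is not None and fever_celsius > 38.0)
        + int(inflammatory_markers_elevated == "yes")
        + int(two_stage_course)
    )
    temporal = duration_days > 10 or worsening_after_day5
    if temporal and n_signs >= 3:
        return "ABRS"
    if temporal:
        return "POST_VIRAL_ARS"
    return "COMMON_COLD"


FLAT_THERAPY = {
    "COMMON_COLD": "DECONGESTANT",
    "POST_VIRAL_ARS": "DECONGESTANT_PLUS_INCS",
    "ABRS": "ANTIBIOTIC",
    "CRS": "INCS",
    "CRS_MACROLIDE_ELIGIBLE": "MACROLIDE_TRIAL",
    "CRS_COMPLICATION": "ANTIBIOTIC",
}
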