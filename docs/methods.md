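# Methods

## The decision model

The package implements a knowledge-based clinical decision support model
for rhinosinusitis: a knowledge base of declarative if–then rules, a
forward-chaining inference engine, and a fixed diagnosis→therapy mapping.
The knowledge base encodes the EPOS 2012 criteria.

**Course.** Duration in days is the canonical temporal input (no calendar
arithmetic). "Less than 12 weeks" defines the acute course, so the closure
at exactly 84 days is assigned to the chronic side: `duration_days < 84` is
acute, `>= 84` chronic.

**Acute branch.** The temporal criterion is `duration_days > 10 OR
worsening_after_day5` — both read literally as strict bounds, so day 10
without worsening does not qualify. The five cardinal signs of bacterial
superinfection are: discoloured/purulent discharge, severe local pain,
fever strictly above 38.0 °C, elevated ESR/CRP, and a two-stage course.
Temporal criterion plus ≥ 3 signs ⇒ acute bacterial rhinosinusitis (ABRS);
temporal criterion alone ⇒ post-viral ARS; otherwise common cold. The
one-sided-predominance flags for discharge and pain are recorded but do not
enter the sign count: the guideline lists predominance as a qualifier of
those signs, not as separate signs.

**Chronic branch.** A postoperative purulent complication dominates
(antibiotic indication in its own right), then the macrolide triple —
refractory to intranasal corticosteroid, no nasal polyps, low total IgE —
(macrolide trial), then baseline CRS (intranasal corticosteroid).

**Missing data.** Tri-state findings (`yes`/`no`/`unknown`) treat `unknown`
as not satisfying any predicate. This is deliberately conservative: missing
CRP or IgE data can never add an antibiotic indication.

## The inference engine

Rules are conjunctions of named antecedent tokens implying a single fact.
Antecedents may name a built-in clinical predicate (evaluated once on the
profile) or a previously derived fact; facts are only added, never
retracted, so chaining reaches a unique monotone fixpoint independent of
rule order. The fired-rule log is reported sorted by `(priority, rule_id)`,
making the whole output — not just the fact set — invariant under rule
permutation.

The engine derives *every* diagnosis fact consistent with the profile (a
bacterial acute case also satisfies the post-viral and common-cold
antecedents) and resolves the single reported category by clinical
precedence: complication > macrolide-eligible > chronic baseline on the
chronic branch, bacterial > post-viral > common cold on the acute branch.
This was a genuinely open design point — the alternative is encoding
mutual exclusion into the antecedents — and precedence resolution was
chosen because it keeps each rule a faithful statement of its criterion and
keeps the rule file editable without re-deriving negations. The knowledge
base ships as YAML (`rhinoguide/rulesets/epos2012.yaml`) so it can be
revised (e.g., for a guideline update) without code changes.

## Therapy mapping

Total on the six categories: common cold → decongestant; post-viral ARS →
decongestant + INCS; ABRS → antibiotic; CRS → INCS; macrolide-eligible CRS
→ macrolide trial; CRS with complication → antibiotic. `antibiotic_indicated`
is true exactly for ABRS, the complication, and the macrolide trial. No
drug names, doses or durations are modelled.

## The synthetic cohort generator

The original 1465-patient cohort is not publicly deposited; only its
category composition is published. The generator therefore samples raw
symptom vectors uniformly within each category's defining ranges:

* common cold: duration 1–10 d, no worsening, 0–2 cardinal signs (the
  temporal criterion cannot hold, so signs are capped at 2 only for
  clarity);
* post-viral: duration 11–83 d (80% of draws) or 6–10 d with worsening
  (20%), 0–2 signs;
* ABRS: same temporal sampling, 3–5 signs;
* chronic categories: duration 84–365 d; baseline CRS has the macrolide
  triple explicitly broken when it would arise by chance (refractoriness is
  drawn at rate 0.25); the macrolide-eligible and complication categories
  set their defining flags.

Fever is drawn in (38.0, 40.5] °C when the fever sign is present and in
[36.5, 38.0] otherwise, so the strict 38 °C threshold separates the two
exactly. The `study_replica` preset uses the published composition —
335/186/101 acute, 830 baseline CRS, and the 13 antibiotic-treated chronic
cases split 7 macrolide-eligible / 6 postoperative complication (the
published totals fix only the 13; the 7/6 split is a package choice, and
any split preserves every reported percentage).

**Specialist overrides** model reference decisions departing from the
guideline for reasons outside the engine's inputs (immunosuppression,
anticancer therapy, pre-transplant focus-of-infection search, pathological
ostiomeatal unit, metachronous purulent infection). An override forces the
reference label to ANTIBIOTIC. Overrides are drawn uniformly without
replacement from patients whose guideline therapy is *not* already
ANTIBIOTIC: an "override" on a patient already receiving antibiotics would
change nothing, so restricting the pool makes every override a genuine
engine/specialist disagreement and makes concordance exactly
`(n − overrides) / n`. The recorded override reason is informational and
never enters engine logic.

**What the generator does not emulate:** epidemiological correlations
between symptoms, age/sex structure, severity grading, seasonal effects,
and measurement noise in the reference labels. Passing tests therefore
demonstrate that the rule engine implements the stated criteria exactly and
that the published percentages follow from the published category counts —
not that the engine would reach 90.2% agreement on real clinical records.
The 143-override concordance run is an illustrative arithmetic
reconstruction (143 is the discordant count that yields 90.2% of 1465 to
one decimal), not a recovery of the original data.

## Evaluation and rounding

Concordance and all percentages are computed as exact rationals
(`fractions.Fraction`) and rounded only for display, half-up (ties away
from zero), matching how the study tables print: one decimal within the
acute and chronic blocks and for concordance, two decimals for the overall
antibiotic fraction. "Antibiotic" pooling in the distribution tables counts
`antibiotic_indicated` therapies (plain antibiotic and macrolide trial
together). The confusion matrix crosses reference labels (rows) with
engine labels (columns); its total equals the cohort size.

## Problem sizes and determinism

The replica cohort is 1465 patients and evaluates in well under a second.
The exhaustive oracle-equivalence test covers all 36 288 valid profiles on
the boundary grid (durations {0, 5, 6, 10, 11, 83, 84, 85} × worsening ×
sign combinations with fever ∈ {none, 38.0, 38.6} × chronic modifiers).
Generator round-trip tests use 200 samples per category per seed over three
seeds. All randomness flows through a single `numpy` generator seeded from
the cohort spec; identical specs produce byte-identical cohort files.

## Known limitations

* The decision tree is reconstructed from the stated criteria; the original
  system's exact tree and input form are not published. Severity grading
  (e.g., VAS), part of full EPOS but absent from the criteria implemented
  here, is deliberately omitted rather than guessed.
* Red-flag/complication referral logic beyond the postoperative purulent
  complication is out of scope, as are drug selection, dosing, allergy
  checking, and EHR integration.
* The evaluator reports a raw agreement proportion only; no confidence
  intervals or chance-corrected agreement statistics.
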