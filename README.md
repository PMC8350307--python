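# rhinoguide

Guideline-based clinical decision support for rhinosinusitis: a declarative
EPOS 2012 knowledge base, a generic forward-chaining rule engine, a therapy
recommender, a synthetic cohort generator, and a clinician-concordance
evaluator.

## The problem

Rhinosinusitis is among the most common reasons antibiotics are prescribed
in primary care, yet most acute cases resolve without them. The EPOS
(European Position Paper on Rhinosinusitis and Nasal Polyps) 2012 guideline
restricts antibiotic therapy to a narrow set of presentations:

* **Course.** Symptoms lasting less than 12 weeks (< 84 days) are acute
  (ARS); 84 days or more is chronic (CRS).
* **Acute bacterial rhinosinusitis (ABRS).** Antibiotics are considered in
  ARS only when a *temporal criterion* holds — symptoms lasting more than
  10 days, or worsening after day 5 — **and** at least 3 of the 5 cardinal
  signs of bacterial superinfection are present: discoloured/purulent
  discharge, severe local pain, fever > 38 °C, raised ESR/CRP, and a
  two-stage ("double-sickening") course. ARS meeting only the temporal
  criterion is post-viral (decongestant + intranasal corticosteroid);
  anything shorter is a common cold (decongestant alone).
* **Chronic disease.** The drug of choice is an intranasal corticosteroid
  (INCS). A macrolide trial is reserved for refractory, polyp-free CRS with
  low total serum IgE; a postoperative purulent complication is an
  antibiotic indication in its own right.

`rhinoguide` encodes these criteria as a declarative YAML rule set
interpreted by a forward-chaining inference engine: facts derived from a
patient's symptom vector grow monotonically to a fixpoint, every consistent
diagnosis fact is derived, and the strongest one by clinical precedence
(complication > macrolide-eligible > chronic baseline; bacterial >
post-viral > common cold) becomes the diagnosis. Unknown findings never
count toward an antibiotic indication.

Because the retrospective cohort behind the published evaluation is not
deposited, the package ships a synthetic cohort generator that emulates its
published category structure (335 common colds, 186 post-viral and 101
bacterial acute cases; 830 chronic cases on INCS and 13 antibiotic-treated
chronic cases; 1465 patients total). The generator emits raw symptom
vectors, not labels, so every downstream statistic is produced by the
classifier actually re-deriving each category.

## Worked example

Classify a patient presenting with 14 days of symptoms, purulent discharge,
severe facial pain and fever 38.6 °C:

```python
import rhinoguide as rg

profile = rg.validate_profile({
    "patient_id": "p1",
    "duration_days": 14,
    "discoloured_discharge": "true",
    "severe_local_pain": "true",
    "fever_celsius": "38.6",
})
diagnosis = rg.infer(profile)
plan = rg.recommend(diagnosis)
print(diagnosis.category.value, plan.therapy.value, plan.antibiotic_indicated)
```

prints

```
ABRS ANTIBIOTIC True
```

— the temporal criterion holds (14 > 10 days) and three cardinal signs are
present, so this is acute bacterial disease and antibiotics are indicated.

From the shell, replicate the retrospective study on a synthetic cohort
(1465 patients, 143 specialist overrides injected by default):

```
$ rhinoguide replicate-study --seed 1
block	therapy	count	percent
ARS	DECONGESTANT	335	53.9
ARS	DECONGESTANT_PLUS_INCS	186	29.9
ARS	ANTIBIOTIC	101	16.2
ARS	antibiotic_indicated	101	16.2
CRS	INCS	830	98.5
CRS	MACROLIDE_TRIAL	7	0.8
CRS	ANTIBIOTIC	6	0.7
CRS	antibiotic_indicated	13	1.5
overall	antibiotic_indicated	114	7.78
overall	concordance	1322/1465	90.2
```

Reading the table: among the 622 acute patients, 53.9% need only a
decongestant, 29.9% add an intranasal corticosteroid, and 16.2% meet the
bacterial criteria; 98.5% of the 843 chronic patients stay on INCS; only
7.78% of the whole cohort (114/1465) carry any antibiotic indication. The
final row is engine/specialist concordance: each injected override models a
specialist prescribing antibiotics for reasons outside the engine's inputs
(immunosuppression, pre-transplant focus search, …), so 143 overrides leave
1322/1465 = 90.2% agreement.

Other subcommands: `rhinoguide classify --input patients.csv`,
`rhinoguide simulate --preset study_replica --seed 7 --output cohort.csv`,
`rhinoguide evaluate --input cohort.csv`. A custom knowledge base can be
supplied with `--ruleset rules.yaml` (same schema as the shipped
`rhinoguide/rulesets/epos2012.yaml`).

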