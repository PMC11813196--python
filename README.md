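# lbp-cds — rule-based clinical decision support for low back pain

Most low back pain (LBP) leaves the clinic labelled "nonspecific", a
diagnosis that informs neither the patient nor the treatment plan, even
though the literature distinguishes specific, treatable contributors.
`lbp-cds` implements a clinician-facing decision support engine for
point-of-care LBP evaluation: an adaptive interview/examination instrument,
Boolean diagnostic rules producing evidence-graded *working diagnoses* with
traceable supporting findings, and diagnosis-linked treatment and
patient-education planning. It is intended for clinical-informatics
developers and researchers prototyping or studying rule-based LBP decision
support; it is not a medical device and screens for no red-flag pathology.

## The model

All clinical content lives in a declarative knowledge base (JSON, YAML
accepted). The shipped default encodes 44 interview/examination items and
12 working diagnoses — 3 *macrodiagnoses* by pain mechanism (nociceptive,
neuropathic, nociplastic) and 9 *microdiagnoses* within them (myofascial,
facet joint, sacroiliac joint, discogenic, radicular pain, radiculopathy,
neurogenic claudication, piriformis syndrome, central sensitization).

* **Adaptive enabling.** Each item `i` carries an enabling rule `E_i`, a
  Boolean expression over other items' findings; `i` is presented only
  while `E_i(F)` holds against the active findings `F`. 13 interview items,
  1 examination item, and the synthesis item are always enabled; the other
  13 + 16 open only when indicated (e.g. recording *sensory changes in a
  nerve root distribution* enables the 8 interview + 6 examination items
  that clarify the neuropathic microdiagnoses). The enabling graph is
  required to be acyclic, and the active findings are the greatest
  self-consistent subset of what was recorded (fixed point of iterated
  removal), so enablement is a pure function of the findings map.
* **Diagnosis rules and grading.** A diagnosis `d` triggers when its rule
  `R_d(F)` holds (e.g. piriformis syndrome is a 5-way OR over its printed
  findings). Its evidence grade on the 1–5 *likeliness scale* is
  `ceil(s_max · k / n)` clamped to ≥ 1, where `k` of the `n` declared
  evidence atoms are satisfied — 1 reads "less likely", 5 "more likely";
  working diagnoses are deliberately non-definitive.
* **Suppression.** Knowledge-base-declared competitor pairs model
  explaining-away: `d` is rejected when its declared competitor `c` is also
  triggered with strictly greater evidence count (single pass, counts
  untouched). Every inference result carries its supporting findings for
  hover-style traceability.

## Worked example

```bash
python examples/rank_and_suppression.py
```

replays the shipped multifactorial scenario (evidence touching all three
macrodiagnoses) and prints:

```
[#####] 5/5  Neurogenic claudication  (5 findings)
[####.] 4/5  Nociplastic pain  (3 findings)
[####.] 4/5  Neuropathic pain  (2 findings)
[###..] 3/5  Nociceptive pain  (2 findings)
...
[####.] 4/5  Piriformis syndrome  (4 findings)  REJECTED: rejected in favor
of Neurogenic claudication: overlapping presentation with stronger evidence
(5 vs 4 findings)
```

Reading: neurogenic claudication satisfies 5 of its 6 evidence atoms
(grade ceil(5·5/6) = 5), nociplastic pain 3 of 4 (grade 4); piriformis
syndrome triggers on 4 of its 5 findings but is rejected because its
declared competitor explains the overlapping buttock/leg presentation with
strictly stronger evidence. Other examples cover adaptive enablement
(`adaptive_enablement.py`), care-plan/note export (`care_plan_export.py`),
and System Usability Scale scoring (`sus_scoring.py`).

The same surface is scriptable from a shell:

```bash
lbp-cds validate                      # knowledge-base validation, exit 0 iff clean
lbp-cds census --json                 # structural counts (44 items, 12 diagnoses)
lbp-cds scenario --name radicular     # replay a shipped scenario
lbp-cds scenario --seed 7             # generate + replay a synthetic encounter
lbp-cds evaluate findings.json --json # batch inference on a findings document
lbp-cds interview                     # interactive adaptive interview
lbp-cds sus responses.csv             # SUS questionnaire summary
```

## Layout

* `src/lbp_cds/` — library: `knowledge_base`, `expressions`, `session`,
  `inference`, `plan`, `scenarios`, `sus`, `cli`
* `src/lbp_cds/data/` — default knowledge base and scenario fixtures
* `examples/` — one short narrative script per capability
* `docs/methods.md` — model, conventions, design decisions, limitations
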