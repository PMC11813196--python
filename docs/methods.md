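# Methods

## The model

`lbp-cds` is a deterministic, knowledge-base-driven rule engine for low
back pain (LBP) evaluation. There is no probabilistic or learned component:
every behavior is a function of the declarative knowledge base (KB) and the
recorded findings. The KB holds five entity classes — input items with
enabling rules, working diagnoses with trigger rules and evidence atoms,
suppression pairs, treatments, and education materials — and the engine
modules interpret it without embedded clinical policy. This keeps clinical
review on a diffable document and makes inference reproducible: identical
findings always yield identical, identically ordered output.

### Items and adaptive enabling

An item is an interview question, an examination finding, or a synthesis
judgment, with a binary response domain (`present`/`absent`) by default.
"Unanswered" is the absence of a record, not a third response: the
screenshots-style toggle semantics keep Boolean evaluation two-valued.
Each item carries exactly one enabling rule; always-enabled items have the
constant-true rule. The enabling graph (edges from referenced items to the
items they gate) must be acyclic — validation rejects cycles — which
guarantees the fixed-point computation below terminates.

The **active findings** are the greatest subset *S* of the recorded
findings such that every item in *S* is enabled when enablement is
evaluated against *S* itself, computed by iterated removal to a fixed
point. Findings on items that become disabled are *retained but inactive*:
excluded from inference and the summary, restored automatically if the item
is re-enabled. The retained-but-inactive policy is a design choice
(conditional-form-field convention); clearing on disable would also be
defensible but makes exploratory toggling destructive. Because the enabled
set is recomputed from scratch from the findings map on every query,
enablement is order-independent by construction — a property the suite
checks over randomized record/retract sequences.

Display ordering is contractual: interview before examination before
synthesis (paralleling clinical workflow), clusters contiguous in order of
first declaration, declaration order within a cluster.

### Diagnosis rules, the likeliness scale, suppression

A diagnosis triggers when its Boolean rule holds against the active
findings; an atom holds iff the findings record exactly the required
response, so unanswered atoms are false. Consequence worth flagging:
`not(atom)` holds for *unanswered* items as well as for contrary answers.
The rule language supports `and`/`or`/`not`, but the shipped KB is
negation-free — absence of evidence never argues for a diagnosis there.

Evidence strength counts satisfied evidence atoms (every rule atom must be
declared an evidence atom, so triggering and counting draw from the same
findings). The display grade on the anchored 1–5 likeliness scale is
`ceil(scale_max · count / n_atoms)`, clamped to ≥ 1 when triggered and 0
otherwise. The anchors fix only the endpoints; this mapping was chosen
because it is monotone in the count, reaches `scale_max` exactly at full
evidence, and grades a single finding as 1 on a 5-atom rule. Rules with
more atoms than `scale_max` compress monotonically (e.g. 5 of 6 findings →
ceil(25/6) = 5).

Suppression ("rejected by the model") is declared per diagnosis as
competitor pairs in the KB, not inferred from shared atoms: whether symptom
*overlap* alone should reject, or only stronger evidence, is a clinical
judgment we keep out of engine code. The engine applies one pass of strict
count dominance — D is suppressed iff D and its declared competitor C are
both triggered and C's pre-suppression evidence count strictly exceeds
D's. Equal counts never suppress; suppression never alters counts or
grades; no transitive chaining (a suppressed competitor still dominates in
the same pass, since dominance reads pre-suppression counts). Ranking is
the total order (unsuppressed first, grade desc, count desc, KB declaration
order), so ties are broken reproducibly.

Clinicians may accept any diagnosis, including untriggered ones; such
overrides are stored with an explicit marker and surfaced in the exported
note rather than blocked — the model advises, the clinician decides.

### Care planning

Treatments declare applicability per diagnosis or via the `ALL` sentinel;
the plan is the union over accepted diagnoses, de-duplicated, each
treatment listing its contributing diagnoses (`ALL` treatments contribute
every accepted diagnosis). Ordering is by breadth of contribution, then KB
order — without published evidence weights, breadth is the only principled
priority, and it is documented as provisional. Education is the
de-duplicated union of per-diagnosis materials. The exported note is a pure
function of (session, evidences, plan); wall-clock time is deliberately
excluded from the note body so identical sessions export byte-identical
text. Markdown/plain text is the printable surface; PDF rendering is a
front-end concern.

## The shipped knowledge base

The default KB encodes 44 items — 13 always-enabled interview, 13
conditional interview, 1 always-enabled examination, 16 conditional
examination, and 1 synthesis item (enabled for all patients) — and 12
diagnoses: 3 macrodiagnoses by pain mechanism (nociceptive, neuropathic,
nociplastic) and 9 microdiagnoses (myofascial, facet joint, sacroiliac
joint, discogenic, radicular pain, radiculopathy, neurogenic claudication,
piriformis syndrome, central sensitization). The piriformis rule is the
5-way OR over radiating ipsilateral leg pain, greater sciatic notch
tenderness, buttock pain, positive straight leg raise, and increased pain
with prolonged sitting; recording nerve-root sensory changes enables
exactly 8 further interview and 6 further examination items. Published
sources for this class of tool print those structural constraints and a
handful of rules and treatment facts, not a complete catalog; the remaining
items, rules, treatments, and education texts here were authored to the
evidence-based LBP classification framework and are flagged
`source: reconstructed` in the KB file. The structural constraints are
enforced by the test suite, so any edit that breaks them fails loudly.

A documented discrepancy in the source material (14 vs 12 working
diagnoses) is resolved in favor of 12 = 3 + 9, the figure consistent with
the diagnosis taxonomy.

## Scenario fixtures and the synthetic generator

Four fictional usability scenarios ship as replayable fixtures — acute
nociceptive pain, chronic nociceptive pain, chronic nociceptive pain with
symptoms of neurogenic claudication, and radicular pain — plus a fifth
multifactorial fixture in which piriformis syndrome triggers and is
rejected in favor of neurogenic claudication. The vignette prose is
authored here (only condition labels were published); what the fixtures pin
down is rank and suppression behavior, which is why tests assert on the
evidence ordering, not the narrative.

The generator emulates an encounter, not an epidemiology: it walks the
enabling graph in deterministic topological order and answers each item
that is enabled at its turn, `present` with probability 0.3 (sparse, mixed
encounters), or — when targeting a diagnosis — the target's evidence atoms
at 0.9, making a k-way OR trigger with probability 1 − 0.1^k. Both
probabilities are exercise settings, configurable per call; they model no
symptom prevalence, comorbidity structure, or response correlation. Because
items are answered only when enabled, every generated script replays
cleanly by construction. Passing tests on generated encounters therefore
demonstrate engine correctness (enablement soundness, monotonicity,
determinism), not clinical realism of the finding patterns.

## Numerical and engineering choices

* Satisfiability checks in validation (unreachable items, untriggerable
  rules) brute-force the referenced items' response domains plus
  "unanswered", capped at 4096 combinations; larger expressions are
  reported as unchecked warnings rather than guessed at.
* Timestamps are ISO-8601 UTC; sessions are single-writer JSON documents
  with whole-file replace, and loading enforces KB-version equality rather
  than attempting migration.
* Randomized suites use fixed seeds (hypothesis with bounded example
  counts; 1,000-seed replay sweeps, which complete in seconds on the
  44-item KB). Problem sizes — expressions up to 6 atoms checked over all
  assignments, random KBs up to 12 items, sequences up to ~12 operations —
  were chosen to exhaust the relevant structure (every connective, chained
  enablement, ties in ranking) while keeping the default suite fast.
* The System Usability Scale module implements the standard instrument:
  ten items, alternating polarity (odd positive, even negative), score =
  2.5 × Σ contributions ∈ [0, 100] on the 2.5-point lattice; summaries
  report mean/range and the conventional 68 (above-average) and 80
  (top-decile) benchmarks. Input must follow instrument order — no
  polarity auto-detection.

## Limitations

* The engine performs no red-flag pathology screening (fracture, infection,
  malignancy); it presumes that triage has happened.
* Evidence grades are counts mapped to a display scale, not calibrated
  probabilities; they support rapid visual comparison, nothing inferential.
* Suppression covers only KB-declared pairs; the default KB declares the
  single clinically motivated pair (piriformis syndrome vs neurogenic
  claudication).
* Reconstructed KB content is faithful to the structural constraints but is
  not a clinically validated instrument; treatment lists carry no priority
  weighting beyond breadth of contribution.
* No EHR integration, multi-user concurrency, or web front end; the CLI and
  library are the interfaces.
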