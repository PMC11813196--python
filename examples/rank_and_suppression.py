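"""Evidence grading and model-driven rejection on the multifactorial case.

Replays the shipped multifactorial scenario (evidence touching all three
pain-mechanism macrodiagnoses) and prints the ranked working diagnoses.
Each line shows the likeliness grade (1 = less likely ... 5 = more likely,
computed as ceil(scale_max * satisfied_evidence / total_evidence_atoms))
and the satisfied-finding count. Piriformis syndrome triggers on 4 of its 5
findings but is rejected: its declared competitor, neurogenic claudication,
explains the overlapping presentation with strictly stronger evidence.
"""

from lbp_cds import (
    default_kb,
    evaluate_diagnoses,
    multifactorial_scenario,
    replay_scenario,
)

kb = default_kb()
scenario = multifactorial_scenario()
session = replay_scenario(kb, scenario)
print(f"Scenario: {scenario.title}")
print(f"Findings recorded: {len(session.findings)}\n")
for ev in evaluate_diagnoses(kb, session):
    bar = "#" * ev.scale_value + "." * (ev.scale_max - ev.scale_value)
    line = (f"[{bar}] {ev.scale_value}/{ev.scale_max}  {ev.name}"
            f"  ({ev.evidence_count} findings)")
    if ev.suppressed:
        line += f"  REJECTED: {ev.suppression_reason}"
    print(line)
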