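"""From accepted diagnoses to a copy-pasteable clinical note.

Replays the claudication scenario, accepts the two top-ranked working
diagnoses, builds the care plan (treatments de-duplicated across diagnoses,
each listing its contributing diagnoses; education materials unioned), and
prints the exported plain-text note.
"""

from lbp_cds import (
    build_care_plan,
    default_kb,
    evaluate_diagnoses,
    export_note,
    replay_scenario,
    scenario_by_name,
    set_dx_selection,
)

kb = default_kb()
session = replay_scenario(kb, scenario_by_name("nociceptive_with_claudication"))
evidences = evaluate_diagnoses(kb, session)
for ev in evidences[:2]:
    set_dx_selection(session, ev.dx_id, "accepted")
    print(f"accepted: {ev.name} (evidence {ev.scale_value}/{ev.scale_max})")

plan = build_care_plan(kb, session)
print(f"\nplan: {len(plan.treatments)} treatments, "
      f"{len(plan.education)} education materials\n")
print(export_note(session, evidences, plan))
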