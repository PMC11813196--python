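"""Adaptive interview logic: how one macro-level finding opens the
micro-diagnosis clarification items.

Builds a fresh encounter on the shipped knowledge base, records 'Sensory
changes in a nerve root distribution' as present, and reports how many
additional interview and examination items the adaptive logic enables. The
printed deltas (8 interview, 6 examination) are the clarification items for
the neuropathic microdiagnoses: radicular pain, radiculopathy, neurogenic
claudication.
"""

from lbp_cds import default_kb, enabled_items, kb_census, new_session, record_finding

kb = default_kb()
census = kb_census(kb)
print(f"Knowledge base: {census.total_items} items, "
      f"{census.diagnoses_total} diagnoses "
      f"({census.macro} macro + {census.micro} micro)")

session = new_session(kb)
before = {i.item_id for i in enabled_items(session)}
print(f"Fresh session enables {len(before)} items "
      "(always-enabled interview/examination plus the synthesis item).")

trigger = kb.find_item_by_text("sensory changes in a nerve root distribution")
record_finding(session, trigger.item_id, "present")
added = [i for i in enabled_items(session) if i.item_id not in before]
by_phase = {"interview": 0, "examination": 0}
for item in added:
    by_phase[item.phase] += 1
    print(f"  newly enabled [{item.phase}] {item.text}")
print(f"Recording '{trigger.text}' enabled {by_phase['interview']} interview "
      f"and {by_phase['examination']} examination items.")
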