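{
  "scenario_id": "nociceptive_with_claudication",
  "title": "Chronic nociceptive pain with symptoms of neurogenic claudication",
  "narrative": "A 68-year-old retired farmer has had low back pain for over a year, aggravated by loading and relieved by rest, with familiar pain on lumbar palpation. For the past months both legs become heavy and tingly after walking a few blocks; sitting or leaning on a cart brings relief. Sustained lumbar extension reproduces the leg symptoms in the office. Fictional vignette authored against the default knowledge base (reconstructed; condition label only was published).",
  "findings_script": [
    ["aggravated_by_loading", "present"],
    ["relieved_by_rest", "present"],
    ["duration_over_3_months", "present"],
    ["sensory_nerve_root_changes", "present"],
    ["leg_symptoms_on_walking", "present"],
    ["relief_with_sitting_flexion", "present"],
    ["bilateral_leg_symptoms", "present"],
    ["lumbar_palpation_tenderness", "present"],
    ["sustained_extension_reproduction", "present"],
    ["treadmill_standing_provocation", "present"]
  ],
  "expected_top_dx": ["neurogenic_claudication", "nociceptive_pain"],
  "expected_suppressed": []
}
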