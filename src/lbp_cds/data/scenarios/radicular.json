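{
  "scenario_id": "radicular",
  "title": "Radicular pain",
  "narrative": "A 42-year-old nurse developed sharp pain radiating from the low back down the right leg below the knee, with tingling along the outer calf, worse with coughing. The leg pain exceeds the back pain. Straight leg raise reproduces the leg pain and sensory testing shows a dermatomal deficit; strength is preserved. Fictional vignette authored against the default knowledge base (reconstructed; condition label only was published).",
  "findings_script": [
    ["radiating_leg_pain", "present"],
    ["sensory_nerve_root_changes", "present"],
    ["burning_shooting_quality", "present"],
    ["leg_worse_than_back", "present"],
    ["dermatomal_numbness", "present"],
    ["cough_sneeze_aggravation", "present"],
    ["reported_leg_weakness", "absent"],
    ["straight_leg_raise", "present"],
    ["dermatomal_sensory_deficit", "present"],
    ["myotomal_weakness", "absent"]
  ],
  "expected_top_dx": ["radicular_pain"],
  "expected_suppressed": []
}
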