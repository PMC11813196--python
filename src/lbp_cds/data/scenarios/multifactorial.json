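{
  "scenario_id": "multifactorial",
  "title": "Multifactorial: neurogenic claudication with overlying nociplastic pain",
  "narrative": "A complex presentation with evidence touching all three macrodiagnoses: mechanical aggravation and palpation tenderness (nociceptive), radiating leg pain with nerve-root sensory changes and strong walking/standing-provoked, flexion-relieved bilateral leg symptoms (neuropathic, favoring neurogenic claudication), plus widespread, disproportionate, sleep-disturbing pain (nociplastic). Buttock pain, sitting intolerance, and sciatic notch tenderness also trigger piriformis syndrome, which the model rejects because the overlapping presentation carries stronger evidence for neurogenic claudication. Fictional vignette authored against the default knowledge base (reconstructed).",
  "findings_script": [
    ["aggravated_by_loading", "present"],
    ["radiating_leg_pain", "present"],
    ["sensory_nerve_root_changes", "present"],
    ["widespread_pain", "present"],
    ["disproportionate_pain", "present"],
    ["sleep_disturbance", "present"],
    ["prolonged_sitting_pain", "present"],
    ["buttock_pain", "present"],
    ["lumbar_palpation_tenderness", "present"],
    ["leg_symptoms_on_walking", "present"],
    ["relief_with_sitting_flexion", "present"],
    ["bilateral_leg_symptoms", "present"],
    ["sustained_extension_reproduction", "present"],
    ["treadmill_standing_provocation", "present"],
    ["sciatic_notch_tenderness", "present"]
  ],
  "expected_top_dx": ["neurogenic_claudication", "nociplastic_pain"],
  "expected_suppressed": ["piriformis_syndrome"]
}
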