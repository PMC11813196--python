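{
  "scenario_id": "chronic_nociceptive",
  "title": "Chronic nociceptive pain",
  "narrative": "A 55-year-old office manager reports eight months of aching low back pain, worse with activity and prolonged postures, easing with rest and position change. No leg symptoms. Palpation of the lumbar spine reproduces familiar pain. Fictional vignette authored against the default knowledge base (reconstructed; condition label only was published).",
  "findings_script": [
    ["aggravated_by_loading", "present"],
    ["relieved_by_rest", "present"],
    ["onset_with_activity", "absent"],
    ["duration_over_3_months", "present"],
    ["morning_stiffness", "present"],
    ["lumbar_palpation_tenderness", "present"],
    ["myofascial_trigger_point", "absent"]
  ],
  "expected_top_dx": ["nociceptive_pain"],
  "expected_suppressed": []
}
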