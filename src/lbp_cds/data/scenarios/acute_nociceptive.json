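{
  "scenario_id": "acute_nociceptive",
  "title": "Acute nociceptive pain",
  "narrative": "A 38-year-old warehouse worker felt sharp low back pain while lifting a pallet two days ago. Pain worsens with bending and lifting, eases when lying down, and does not travel into the legs. Lumbar palpation reproduces the familiar pain. Fictional vignette authored against the default knowledge base (reconstructed; condition label only was published).",
  "findings_script": [
    ["aggravated_by_loading", "present"],
    ["relieved_by_rest", "present"],
    ["onset_with_activity", "present"],
    ["duration_over_3_months", "absent"],
    ["prior_episodes", "absent"],
    ["lumbar_palpation_tenderness", "present"],
    ["centralization_with_repeated_movement", "absent"],
    ["facet_loading_reproduction", "absent"]
  ],
  "expected_top_dx": ["nociceptive_pain"],
  "expected_suppressed": []
}
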