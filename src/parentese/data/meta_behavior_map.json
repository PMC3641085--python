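{
  "_comment": "Synthetic ICBS item -> meta-behavior map. Item codes are artifact-defined stand-ins for the behavioral coding grid (caregiver solicitation items, infant engagement items); the meta-behavior level (5 caregiver, 6 infant categories) is the analysis unit.",
  "caregiver": {
    "cg_vocalisation": "vocal_solicitation",
    "cg_calls_name": "vocal_solicitation",
    "cg_touch": "touching",
    "cg_tickles": "touching",
    "cg_gesture": "gestural_solicitation",
    "cg_shows_object": "gestural_solicitation",
    "cg_reg_up": "regulation_up",
    "cg_reg_down": "regulation_down"
  },
  "infant": {
    "inf_looks_object": "toward_object",
    "inf_manipulates_object": "toward_object",
    "inf_vocalises": "expressive",
    "inf_babbles": "expressive",
    "inf_joint_attention": "inter_subjective",
    "inf_imitates": "inter_subjective",
    "inf_seeks_contact": "active",
    "inf_reaches_person": "active",
    "inf_looks_person": "receptive",
    "inf_smiles_person": "receptive",
    "inf_orients_to_voice": "exploratory",
    "inf_explores_scene": "exploratory"
  },
  "aliases": {
    "vocalizations": "expressive",
    "seeking_people": "active",
    "orienting": "exploratory"
  }
}
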