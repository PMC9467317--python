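{
  "response_outputs": {
    "Survival": "survival",
    "Apoptosis": "apoptosis",
    "Necroptosis": "necroptosis"
  },
  "resolution_rules": [
    {
      "comment": "MOMP inhibition (BCL-2 sequestering active BAX) together with extrinsic caspase-3 activation still executes apoptosis through the extrinsic branch",
      "requires_transitions": ["T48", "T42"],
      "requires_labels": ["apoptosis"],
      "label": "apoptosis"
    }
  ]
}
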