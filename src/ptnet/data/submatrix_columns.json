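{
  "comment": "21 selected pathway entities (complexes and key species) for the knockout submatrix view",
  "columns": [
    "CI", "CI:CYLD", "CI:A20", "TRADD:RIP1", "CIIa", "CIIb", "CIIb:cFLIPL",
    "CIIb:cFLIPs", "CASP8", "CASP3", "XIAP:CASP3", "BCL-2:BAX", "Apoptosome",
    "CASP9", "XIAP:CASP9", "SMAC:XIAP", "RIP1:RIP3", "MLKL_PM", "NF-kB_n",
    "NF-kB:IkB", "IKKa"
  ]
}
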