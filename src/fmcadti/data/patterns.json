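{
  "benzene": ["c1ccccc1", "C1=CC=CC=C1"],
  "oxygen_chain": ["COC"],
  "carboxyl": ["C(=O)O"]
}
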