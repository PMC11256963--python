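{
  "A": "A", "G": "A", "V": "A",
  "I": "B", "L": "B", "F": "B", "P": "B",
  "Y": "C", "M": "C", "T": "C", "S": "C",
  "H": "D", "N": "D", "Q": "D", "W": "D",
  "R": "E", "K": "E",
  "D": "F", "E": "F",
  "C": "G"
}
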