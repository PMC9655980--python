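{
  "comment": "Atomic polarizabilities in 1e-24 cm^3; carbon is the scaling reference for the mean-polarizability descriptor.",
  "reference_element": "C",
  "values": {
    "H": 0.667,
    "B": 3.03,
    "C": 1.76,
    "N": 1.10,
    "O": 0.802,
    "P": 3.63,
    "S": 2.90,
    "F": 0.557,
    "Cl": 2.18,
    "Br": 3.05,
    "I": 5.35
  }
}
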