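{
  "comment": "Potential-pharmacophore-point (PPP) typing rules. Each entry is a list of SMARTS; an atom receives the label when it matches any pattern (for 'negative', all N/O atoms inside a matched group are labelled). 'lipophilic' is derived: carbon or halogen atoms with no neighbour labelled donor/acceptor/negative.",
  "donor": [
    "[#7;!H0]",
    "[#8;!H0]"
  ],
  "acceptor": [
    "[#8;!+;!$([#8]~[#7]~[#8;D1])]",
    "[#7;!+;X1,X2;!$([#7]~[#8;D1])]",
    "[#7;!+;X3;!$([nX3]);!$([#7]~[#8;D1]);!$([#7][#6]=[#8,#16])]"
  ],
  "negative": [
    "[#6](=[#8;D1])[#8;D1,$([#8;H1])]",
    "[#16](=[#8;D1])(=[#8;D1])[#8;D1,$([#8;H1])]",
    "[#15](=[#8;D1])[#8;D1,$([#8;H1])]",
    "[#6]1=,:[#7][#7]=,:[#7][#7]1",
    "c1nnnn1"
  ],
  "positive": [
    "[#7;+;!$([#7]~[#8;D1])]"
  ],
  "lipophilic_elements": ["C", "F", "Cl", "Br", "I"]
}
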