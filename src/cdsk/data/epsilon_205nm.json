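{
  "wavelength_nm": 205,
  "source": "Anthis & Clore (2013) Protein Sci. 22:851-858, sequence-based protein extinction at 205 nm",
  "notes": "Side-chain contributions in M^-1 cm^-1; residues absent from the table contribute 0. 'peptide_bond' is the backbone amide contribution per bond; 'cystine' is the contribution of one disulfide-bonded cysteine pair, replacing the two reduced-cysteine (C) side-chain terms.",
  "peptide_bond": 2780,
  "cystine": 820,
  "residues": {
    "A": 0, "R": 1940, "N": 300, "D": 0, "C": 690,
    "Q": 400, "E": 0, "G": 0, "H": 5200, "I": 0,
    "L": 0, "K": 0, "M": 1830, "F": 8600, "P": 0,
    "S": 0, "T": 0, "W": 20400, "Y": 6080, "V": 0
  }
}
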