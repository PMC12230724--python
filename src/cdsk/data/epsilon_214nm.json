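{
  "wavelength_nm": 214,
  "source": "Kuipers & Gruppen (2007) J. Agric. Food Chem. 55:5445-5451, additive peptide extinction scheme at 214 nm",
  "notes": "Side-chain contributions in M^-1 cm^-1; residues absent from the table contribute 0. The proline value applies to internal (tertiary-amide) proline residues. 'peptide_bond' is the backbone amide contribution per bond; 'cystine' is the contribution of one disulfide-bonded cysteine pair, replacing the two reduced-cysteine side-chain terms (this scheme does not distinguish oxidation states, so it equals 2x the Cys value).",
  "peptide_bond": 923,
  "cystine": 450,
  "residues": {
    "A": 0, "R": 102, "N": 136, "D": 0, "C": 225,
    "Q": 142, "E": 0, "G": 0, "H": 5125, "I": 0,
    "L": 0, "K": 0, "M": 980, "F": 5200, "P": 2675,
    "S": 0, "T": 0, "W": 29050, "Y": 5375, "V": 0
  }
}
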