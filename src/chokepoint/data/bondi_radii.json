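{
  "_comment": "Bondi (1964) van der Waals radii in Angstrom; version 1. Immutable at run time.",
  "version": 1,
  "radii": {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "FE": 2.00,
    "MN": 2.00,
    "CA": 2.31
  }
}
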