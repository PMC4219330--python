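{
  "name": "rose1985-mean-max-asa",
  "units": "A^2",
  "reference": "Rose GD, Geselowitz AR, Lesser GJ, Lee RH, Zehfus MH (1985) Hydrophobicity of amino acid residues in globular proteins. Science 229:834-838.",
  "values": {
    "A": 118.1,
    "R": 256.0,
    "N": 165.5,
    "D": 158.7,
    "C": 146.1,
    "Q": 193.2,
    "E": 186.2,
    "G": 88.1,
    "H": 202.5,
    "I": 181.0,
    "L": 193.1,
    "K": 225.8,
    "M": 203.4,
    "F": 222.8,
    "P": 146.8,
    "S": 129.8,
    "T": 152.5,
    "W": 266.3,
    "Y": 236.8,
    "V": 164.5
  }
}
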