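{
  "_comment": "Deleage & Roux (1987) conformational parameters for the four secondary-structure states, as used by the ExPASy ProtScale service. Versioned data file: the single source of truth for the propensity scales, swappable.",
  "version": 1,
  "scales": {
    "alpha_helix": {
      "A": 1.489, "R": 1.224, "N": 0.772, "D": 0.924, "C": 0.966,
      "Q": 1.164, "E": 1.504, "G": 0.510, "H": 1.003, "I": 1.003,
      "L": 1.236, "K": 1.172, "M": 1.363, "F": 1.195, "P": 0.492,
      "S": 0.739, "T": 0.785, "W": 1.090, "Y": 0.787, "V": 0.990
    },
    "beta_sheet": {
      "A": 0.709, "R": 0.920, "N": 0.604, "D": 0.541, "C": 1.191,
      "Q": 0.840, "E": 0.567, "G": 0.657, "H": 0.863, "I": 1.799,
      "L": 1.261, "K": 0.721, "M": 1.210, "F": 1.393, "P": 0.354,
      "S": 0.928, "T": 1.221, "W": 1.306, "Y": 1.266, "V": 1.965
    },
    "beta_turn": {
      "A": 0.788, "R": 0.912, "N": 1.572, "D": 1.197, "C": 0.965,
      "Q": 0.997, "E": 1.149, "G": 1.860, "H": 0.970, "I": 0.240,
      "L": 0.670, "K": 1.302, "M": 0.436, "F": 0.624, "P": 1.415,
      "S": 1.316, "T": 0.739, "W": 0.546, "Y": 0.795, "V": 0.387
    },
    "coil": {
      "A": 0.824, "R": 0.893, "N": 1.167, "D": 1.197, "C": 0.953,
      "Q": 0.947, "E": 0.761, "G": 1.251, "H": 1.068, "I": 0.886,
      "L": 0.810, "K": 0.897, "M": 0.810, "F": 0.797, "P": 1.540,
      "S": 1.130, "T": 1.148, "W": 0.941, "Y": 1.109, "V": 0.772
    }
  }
}
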