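{
  "kyte_doolittle": {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2
  },
  "parker_hydrophilicity": {
    "A": 2.1, "R": 4.2, "N": 7.0, "D": 10.0, "C": 1.4,
    "Q": 6.0, "E": 7.8, "G": 5.7, "H": 2.1, "I": -8.0,
    "L": -9.2, "K": 5.7, "M": -4.2, "F": -9.2, "P": 2.1,
    "S": 6.5, "T": 5.2, "W": -10.0, "Y": -1.9, "V": -3.7
  },
  "emini_surface_fraction": {
    "A": 0.49, "R": 0.95, "N": 0.81, "D": 0.78, "C": 0.26,
    "Q": 0.84, "E": 0.84, "G": 0.48, "H": 0.66, "I": 0.34,
    "L": 0.4, "K": 0.97, "M": 0.48, "F": 0.42, "P": 0.75,
    "S": 0.65, "T": 0.7, "W": 0.51, "Y": 0.76, "V": 0.36
  },
  "chou_fasman_helix": {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.7,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.0, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06
  },
  "chou_fasman_sheet": {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.1, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.6,
    "L": 1.3, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.7
  },
  "chou_fasman_turn": {
    "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19,
    "Q": 0.98, "E": 0.74, "G": 1.56, "H": 0.95, "I": 0.47,
    "L": 0.59, "K": 1.01, "M": 0.6, "F": 0.6, "P": 1.52,
    "S": 1.43, "T": 0.96, "W": 0.96, "Y": 1.14, "V": 0.5
  },
  "turn_frequency_i": {
    "A": 0.06, "R": 0.07, "N": 0.161, "D": 0.147, "C": 0.149,
    "Q": 0.074, "E": 0.056, "G": 0.102, "H": 0.14, "I": 0.043,
    "L": 0.061, "K": 0.055, "M": 0.068, "F": 0.059, "P": 0.102,
    "S": 0.12, "T": 0.086, "W": 0.077, "Y": 0.082, "V": 0.062
  },
  "turn_frequency_i1": {
    "A": 0.076, "R": 0.106, "N": 0.083, "D": 0.11, "C": 0.053,
    "Q": 0.098, "E": 0.06, "G": 0.085, "H": 0.047, "I": 0.034,
    "L": 0.025, "K": 0.115, "M": 0.082, "F": 0.041, "P": 0.301,
    "S": 0.139, "T": 0.108, "W": 0.013, "Y": 0.065, "V": 0.048
  },
  "turn_frequency_i2": {
    "A": 0.035, "R": 0.099, "N": 0.191, "D": 0.179, "C": 0.117,
    "Q": 0.037, "E": 0.077, "G": 0.19, "H": 0.093, "I": 0.013,
    "L": 0.036, "K": 0.072, "M": 0.014, "F": 0.065, "P": 0.034,
    "S": 0.125, "T": 0.065, "W": 0.064, "Y": 0.114, "V": 0.028
  },
  "turn_frequency_i3": {
    "A": 0.058, "R": 0.085, "N": 0.091, "D": 0.081, "C": 0.128,
    "Q": 0.098, "E": 0.064, "G": 0.152, "H": 0.054, "I": 0.056,
    "L": 0.07, "K": 0.095, "M": 0.055, "F": 0.065, "P": 0.068,
    "S": 0.106, "T": 0.079, "W": 0.167, "Y": 0.125, "V": 0.053
  },
  "pka_emboss": {
    "n_terminus": 8.6, "c_terminus": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1
  }
}
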