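{
  "_notes": [
    "Published per-residue propensity tables used by the linear B-cell epitope panel.",
    "All scales are oriented so that LARGER values mean more epitope-prone",
    "(hydrophilic / surface-exposed / flexible / turn-forming / polar).",
    "ponnuswamy_polarity is the Ponnuswamy et al. (1980) average surrounding",
    "hydrophobicity NEGATED, and janin_exposure is the Janin (1979) buried",
    "transfer free energy NEGATED, so both read as exposure/polarity.",
    "kolaskar_tongaonkar_antigenicity keeps its published absolute call rule",
    "(windowed mean propensity > 1.0); emini_accessibility uses the published",
    "product form with the 0.37 mean surface probability normalizer."
  ],
  "parker_hydrophilicity": {
    "statistic": "mean",
    "call_rule": "zscore",
    "reference": "Parker, Guo & Hodges (1986) HPLC-derived hydrophilicity",
    "values": {
      "A": 2.1, "C": 1.4, "D": 10.0, "E": 7.8, "F": -9.2,
      "G": 5.7, "H": 2.1, "I": -8.0, "K": 5.7, "L": -9.2,
      "M": -4.2, "N": 7.0, "P": 2.1, "Q": 6.0, "R": 4.2,
      "S": 6.5, "T": 5.2, "V": -3.7, "W": -10.0, "Y": -1.9
    }
  },
  "emini_accessibility": {
    "statistic": "product",
    "call_rule": "zscore",
    "normalizer": 0.37,
    "reference": "Emini et al. (1985) surface accessibility probabilities",
    "values": {
      "A": 0.49, "C": 0.26, "D": 0.81, "E": 0.84, "F": 0.42,
      "G": 0.48, "H": 0.66, "I": 0.34, "K": 0.97, "L": 0.4,
      "M": 0.48, "N": 0.78, "P": 0.75, "Q": 0.84, "R": 0.95,
      "S": 0.65, "T": 0.7, "V": 0.36, "W": 0.51, "Y": 0.76
    }
  },
  "karplus_schulz_flexibility": {
    "statistic": "mean",
    "call_rule": "zscore",
    "reference": "Karplus & Schulz (1985) normalized backbone B-factors",
    "values": {
      "A": 0.984, "C": 0.906, "D": 1.068, "E": 1.094, "F": 0.915,
      "G": 1.031, "H": 0.95, "I": 0.927, "K": 1.102, "L": 0.935,
      "M": 0.952, "N": 1.048, "P": 1.049, "Q": 1.037, "R": 1.008,
      "S": 1.046, "T": 0.997, "V": 0.931, "W": 0.904, "Y": 0.929
    }
  },
  "kolaskar_tongaonkar_antigenicity": {
    "statistic": "mean",
    "call_rule": "absolute",
    "threshold": 1.0,
    "reference": "Kolaskar & Tongaonkar (1990) antigenic propensity",
    "values": {
      "A": 1.064, "C": 1.412, "D": 0.866, "E": 0.851, "F": 1.091,
      "G": 0.874, "H": 1.105, "I": 1.152, "K": 0.93, "L": 1.25,
      "M": 0.826, "N": 0.776, "P": 1.064, "Q": 1.015, "R": 0.873,
      "S": 1.012, "T": 0.909, "V": 1.383, "W": 0.893, "Y": 1.161
    }
  },
  "chou_fasman_turns": {
    "statistic": "mean",
    "call_rule": "zscore",
    "reference": "Chou & Fasman beta-turn conformational propensity",
    "values": {
      "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.6,
      "G": 1.56, "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59,
      "M": 0.6, "N": 1.56, "P": 1.52, "Q": 0.98, "R": 0.95,
      "S": 1.43, "T": 0.96, "V": 0.5, "W": 0.96, "Y": 1.14
    }
  },
  "ponnuswamy_polarity": {
    "statistic": "mean",
    "call_rule": "zscore",
    "reference": "Ponnuswamy, Prabhakaran & Manavalan (1980) average surrounding hydrophobicity, negated",
    "values": {
      "A": -12.28, "C": -14.93, "D": -10.97, "E": -11.19, "F": -13.43,
      "G": -12.01, "H": -12.84, "I": -14.77, "K": -10.8, "L": -14.1,
      "M": -14.33, "N": -11.0, "P": -11.19, "Q": -11.28, "R": -11.49,
      "S": -11.26, "T": -11.65, "V": -15.07, "W": -12.95, "Y": -13.29
    }
  },
  "janin_exposure": {
    "statistic": "mean",
    "call_rule": "zscore",
    "reference": "Janin (1979) buried/accessible transfer free energy, negated (larger = exposed)",
    "values": {
      "A": -0.3, "C": -0.9, "D": 0.6, "E": 0.7, "F": -0.5,
      "G": -0.3, "H": 0.1, "I": -0.7, "K": 1.8, "L": -0.5,
      "M": -0.4, "N": 0.5, "P": 0.3, "Q": 0.7, "R": 1.4,
      "S": 0.1, "T": 0.2, "V": -0.6, "W": -0.3, "Y": 0.4
    }
  }
}
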