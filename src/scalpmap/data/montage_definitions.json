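{
  "10-20": {
    "midline": {"Fpz": 0.1, "Fz": 0.3, "Cz": 0.5, "Pz": 0.7, "Oz": 0.9},
    "coronal": {"T3": 0.1, "C3": 0.3, "C4": 0.7, "T4": 0.9},
    "ring_left": {
      "q1": {"Fp1": 0.2, "F7": 0.6},
      "q2": {"T5": 0.4, "O1": 0.8}
    },
    "ring_right": {
      "q1": {"Fp2": 0.2, "F8": 0.6},
      "q2": {"T6": 0.4, "O2": 0.8}
    },
    "rows": [
      {"left": "F7", "mid": "Fz", "right": "F8",
       "left_points": {"F3": 0.5}, "right_points": {"F4": 0.5}},
      {"left": "T5", "mid": "Pz", "right": "T6",
       "left_points": {"P3": 0.5}, "right_points": {"P4": 0.5}}
    ]
  },
  "10-10": {
    "midline": {"Fpz": 0.1, "AFz": 0.2, "Fz": 0.3, "FCz": 0.4, "Cz": 0.5,
                "CPz": 0.6, "Pz": 0.7, "POz": 0.8, "Oz": 0.9},
    "coronal": {"T3": 0.1, "C5": 0.2, "C3": 0.3, "C1": 0.4,
                "C2": 0.6, "C4": 0.7, "C6": 0.8, "T4": 0.9},
    "ring_left": {
      "q1": {"Fp1": 0.2, "AF7": 0.4, "F7": 0.6, "FT7": 0.8},
      "q2": {"TP7": 0.2, "T5": 0.4, "PO7": 0.6, "O1": 0.8}
    },
    "ring_right": {
      "q1": {"Fp2": 0.2, "AF8": 0.4, "F8": 0.6, "FT8": 0.8},
      "q2": {"TP8": 0.2, "T6": 0.4, "PO8": 0.6, "O2": 0.8}
    },
    "rows": [
      {"left": "AF7", "mid": "AFz", "right": "AF8",
       "left_points": {"AF3": 0.5}, "right_points": {"AF4": 0.5}},
      {"left": "F7", "mid": "Fz", "right": "F8",
       "left_points": {"F5": 0.25, "F3": 0.5, "F1": 0.75},
       "right_points": {"F2": 0.25, "F4": 0.5, "F6": 0.75}},
      {"left": "FT7", "mid": "FCz", "right": "FT8",
       "left_points": {"FC5": 0.25, "FC3": 0.5, "FC1": 0.75},
       "right_points": {"FC2": 0.25, "FC4": 0.5, "FC6": 0.75}},
      {"left": "TP7", "mid": "CPz", "right": "TP8",
       "left_points": {"CP5": 0.25, "CP3": 0.5, "CP1": 0.75},
       "right_points": {"CP2": 0.25, "CP4": 0.5, "CP6": 0.75}},
      {"left": "T5", "mid": "Pz", "right": "T6",
       "left_points": {"P5": 0.25, "P3": 0.5, "P1": 0.75},
       "right_points": {"P2": 0.25, "P4": 0.5, "P6": 0.75}},
      {"left": "PO7", "mid": "POz", "right": "PO8",
       "left_points": {"PO3": 0.5}, "right_points": {"PO4": 0.5}}
    ]
  }
}
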