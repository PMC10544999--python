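{
  "CYC": {
    "tau1": ["C2B", "C1B", "CHB", "C4A"],
    "tau2": ["C1B", "CHB", "C4A", "C3A"],
    "tau3": ["C2A", "C1A", "CHA", "C4D"],
    "tau4": ["C1A", "CHA", "C4D", "C3D"],
    "tau5": ["C2D", "C1D", "CHD", "C4C"],
    "tau6": ["C1D", "CHD", "C4C", "C3C"]
  },
  "DBV": {
    "tau1": ["C3A", "C4A", "CHA", "C1B"],
    "tau2": ["C4A", "CHA", "C1B", "C2B"],
    "tau3": ["C3B", "C4B", "CHB", "C1C"],
    "tau4": ["C4B", "CHB", "C1C", "C2C"]
  },
  "MBV": {
    "tau1": ["C3", "C4", "C5", "C6"],
    "tau2": ["C4", "C5", "C6", "C7"],
    "tau3": ["C8", "C9", "C10", "C11"],
    "tau4": ["C9", "C10", "C11", "C12"],
    "tau5": ["C13", "C14", "C15", "C16"],
    "tau6": ["C14", "C15", "C16", "C17"]
  },
  "PEB": {
    "tau1": ["C3A", "C4A", "CHA", "C1B"],
    "tau2": ["C4A", "CHA", "C1B", "C2B"],
    "tau3": ["C3B", "C4B", "CHB", "C1C"],
    "tau4": ["C4B", "CHB", "C1C", "C2C"],
    "tau5": ["C3C", "C4C", "CHC", "C1D"],
    "tau6": ["C4C", "CHC", "C1D", "C2D"]
  }
}
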