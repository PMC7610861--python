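{
  "version": "turner2004-like-1.0",
  "comment": "Nearest-neighbor duplex free energies at 37C, kcal/mol. Stack keys are 'XY/ZW' for 5'-XY-3' on the query strand over 3'-ZW-5' on the target strand (pairs X-Z and Y-W); the table is symmetrized in the loader (XY/ZW == WZ/YX). Watson-Crick/Watson-Crick stacks follow the standard Turner 2004 values; wobble-containing stacks are approximate. Loop initiations use Jacobson-Stockmayer extrapolation beyond the tabulated sizes. Duplex initiation is zero, matching hybridization tools that score intermolecular stacking only.",
  "stack": {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
    "GA/UU": -1.30,
    "AU/UG": -1.36,
    "GC/UG": -2.10,
    "GG/UC": -1.50,
    "GG/UU": -0.50,
    "GU/UG": 0.50,
    "UA/GU": -1.00,
    "AG/UU": -0.55,
    "GG/CU": -1.50,
    "CG/GU": -1.40,
    "UG/GU": 0.30
  },
  "bulge": {"1": 3.8, "2": 2.8, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4},
  "internal": {"2": 1.0, "3": 1.4, "4": 1.7, "5": 1.8, "6": 2.0},
  "loop_extrapolation_coef": 1.078,
  "internal_asymmetry": 0.6,
  "internal_asymmetry_max": 3.0,
  "duplex_init": 0.0,
  "terminal_au": 0.45
}
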