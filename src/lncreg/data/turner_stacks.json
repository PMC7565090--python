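{
  "comment": "Nearest-neighbor RNA duplex stack free energies, kcal/mol at 37C (Turner 2004 set). Key 'XY/WZ' is the stack of pair X:Y (5' side) on pair W:Z (3' side), duplex read 5'-XW-3' / 3'-YZ-5'. duplex_init and terminal_au_gu follow the same parameter set.",
  "duplex_init": 4.10,
  "terminal_au_gu": 0.50,
  "stacks": {
    "AU/AU": -0.9, "AU/UA": -1.1, "AU/CG": -2.2, "AU/GC": -2.1, "AU/GU": -0.6, "AU/UG": -1.4,
    "UA/AU": -1.3, "UA/UA": -0.9, "UA/CG": -2.4, "UA/GC": -2.1, "UA/GU": -1.0, "UA/UG": -1.3,
    "CG/AU": -2.1, "CG/UA": -2.1, "CG/CG": -3.3, "CG/GC": -2.4, "CG/GU": -1.4, "CG/UG": -2.1,
    "GC/AU": -2.4, "GC/UA": -2.2, "GC/CG": -3.4, "GC/GC": -3.3, "GC/GU": -1.5, "GC/UG": -2.5,
    "GU/AU": -1.3, "GU/UA": -1.4, "GU/CG": -2.5, "GU/GC": -2.1, "GU/GU": -0.5, "GU/UG": 1.3,
    "UG/AU": -1.0, "UG/UA": -0.6, "UG/CG": -1.5, "UG/GC": -1.4, "UG/GU": 0.3, "UG/UG": -0.5
  }
}
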