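{
  "name": "regions8",
  "kind": "transhemispheric",
  "description": "Eight lateralized regions over the 62-channel 10-10 layout for transhemispheric connectivity. Midline channels (Fpz, AFz, Fz, FCz, Cz, CPz, Pz, POz, Oz, Iz) are unassigned and excluded from aggregation.",
  "regions": [
    {"label": "LF", "channels": ["Fp1", "AF7", "AF3", "F7", "F5", "F3", "F1", "FC1"]},
    {"label": "RF", "channels": ["Fp2", "AF8", "AF4", "F8", "F6", "F4", "F2", "FC2"]},
    {"label": "LT", "channels": ["FT7", "FC5", "T7", "C5", "TP7", "CP5"]},
    {"label": "RT", "channels": ["FT8", "FC6", "T8", "C6", "TP8", "CP6"]},
    {"label": "LP", "channels": ["FC3", "C3", "C1", "CP3", "CP1", "P5", "P3", "P1"]},
    {"label": "RP", "channels": ["FC4", "C4", "C2", "CP4", "CP2", "P6", "P4", "P2"]},
    {"label": "LO", "channels": ["P7", "PO7", "PO3", "O1"]},
    {"label": "RO", "channels": ["P8", "PO8", "PO4", "O2"]}
  ],
  "pairs": [["LF", "RF"], ["LT", "RT"], ["LP", "RP"], ["LO", "RO"]]
}
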