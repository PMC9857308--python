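{
  "name": "regions5",
  "kind": "within",
  "description": "Five lobar regions over a 62-channel 10-10 layout: frontal (F), left temporal (LT), parietal (P), right temporal (RT), occipital (O). Best-effort assignment; override with a custom scheme file if your montage differs.",
  "regions": [
    {"label": "F",  "channels": ["Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8", "FC1", "FCz", "FC2"]},
    {"label": "LT", "channels": ["FT7", "FC5", "T7", "C5", "TP7", "CP5"]},
    {"label": "P",  "channels": ["FC3", "FC4", "C3", "C1", "Cz", "C2", "C4", "CP3", "CP1", "CPz", "CP2", "CP4", "P5", "P3", "P1", "Pz", "P2", "P4", "P6"]},
    {"label": "RT", "channels": ["FT8", "FC6", "T8", "C6", "TP8", "CP6"]},
    {"label": "O",  "channels": ["P7", "P8", "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz"]}
  ]
}
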