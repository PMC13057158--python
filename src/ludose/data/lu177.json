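{
  "schema_version": 1,
  "name": "Lu-177",
  "t_phys_h": 161.6,
  "E_np_MeV": 0.1473,
  "photon_lines": [
    {"keV": 112.95, "yield": 0.0617},
    {"keV": 208.37, "yield": 0.1041},
    {"keV": 249.67, "yield": 0.00212},
    {"keV": 321.32, "yield": 0.00219}
  ]
}
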