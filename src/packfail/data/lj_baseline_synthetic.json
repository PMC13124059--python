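{
  "name": "baseline_synthetic",
  "comment": "Synthetic placeholder Lennard-Jones parameter table (pre-refit). Radii and well depths are plausible literature-style values, NOT any published energy function's parameters; replace with a real table for quantitative comparisons.",
  "types": {
    "CH3": {"radius": 2.01, "well_depth": 0.16},
    "Hapo": {"radius": 1.26, "well_depth": 0.021},
    "OCbb": {"radius": 1.55, "well_depth": 0.16},
    "C_nonpolar_sc": {"radius": 2.0, "well_depth": 0.063},
    "C_polar_sc": {"radius": 2.0, "well_depth": 0.063},
    "CAbb": {"radius": 2.01, "well_depth": 0.063},
    "Npol": {"radius": 1.8, "well_depth": 0.17},
    "OH": {"radius": 1.54, "well_depth": 0.16},
    "other": {"radius": 1.7, "well_depth": 0.05}
  },
  "w_rep": 0.55
}
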