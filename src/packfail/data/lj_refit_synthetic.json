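{
  "name": "refit_synthetic",
  "comment": "Synthetic placeholder Lennard-Jones parameter table (post-refit). Carbon/hydrogen radii are nudged upward and the repulsive weight raised relative to the baseline placeholder, emulating a refit that penalizes overpacking more strongly. NOT any published energy function's parameters.",
  "types": {
    "CH3": {"radius": 2.06, "well_depth": 0.155},
    "Hapo": {"radius": 1.32, "well_depth": 0.021},
    "OCbb": {"radius": 1.55, "well_depth": 0.16},
    "C_nonpolar_sc": {"radius": 2.05, "well_depth": 0.061},
    "C_polar_sc": {"radius": 2.02, "well_depth": 0.063},
    "CAbb": {"radius": 2.03, "well_depth": 0.063},
    "Npol": {"radius": 1.8, "well_depth": 0.17},
    "OH": {"radius": 1.54, "well_depth": 0.16},
    "other": {"radius": 1.7, "well_depth": 0.05}
  },
  "w_rep": 0.63
}
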