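# Synthetic spinal-cord slice profiles per (condition, day).
#
# n_cells are diffuse (non-plaque) cell counts per channel and slice;
# plaque_count_mean is the Poisson mean number of plaques per (dorsal,
# ventro-lateral) sector — 1 vs 4 plaques/slice at the inflammatory peak.
# Diffuse EGFP+ and double-labeled cells are confined to the white-matter
# annulus (no EGFP+ cells in grey matter); EYFP+ cells are disk-wide.
# flag_probs carry the immunostain structure: ~65% of EGFP+ cells Ly6G+ at
# day 14 (60% at day 17), ~70% of double-labeled cells MHCII-high at day 17,
# >90% of EYFP+ cells CX3CR1+ and ~50% of double-labeled cells CX3CR1+.

defaults:
  plaque_cells_mean: 40.0
  plaque_radius: 0.04
  plaque_min_separation: 0.25
  white_matter_annulus: [0.55, 0.95]
  boundary_radius_um: 500.0
  diffuse_compartment: {EGFP: white, double: white, EYFP: all, other: all}

slices:
  - condition: MOG.CFA.PTX
    day: 8
    n_cells: {EGFP: 60, EYFP: 120, double: 5, other: 40}
    plaque_count_mean: [0.2, 0.5]
    plaque_channel_mix: {EGFP: 0.85, EYFP: 0.10, double: 0.05}
    flag_probs:
      EGFP: {Ly6G: 0.70}
      double: {MHCII_hi: 0.30, CX3CR1: 0.50}
      EYFP: {CX3CR1: 0.90}
  - condition: MOG.CFA.PTX
    day: 14
    n_cells: {EGFP: 100, EYFP: 150, double: 30, other: 50}
    plaque_count_mean: [1.0, 4.0]
    plaque_channel_mix: {EGFP: 0.80, EYFP: 0.12, double: 0.08}
    flag_probs:
      EGFP: {Ly6G: 0.65}
      double: {MHCII_hi: 0.50, CX3CR1: 0.50}
      EYFP: {CX3CR1: 0.90}
  - condition: MOG.CFA.PTX
    day: 17
    n_cells: {EGFP: 80, EYFP: 180, double: 60, other: 50}
    plaque_count_mean: [1.0, 4.0]
    plaque_channel_mix: {EGFP: 0.60, EYFP: 0.15, double: 0.25}
    flag_probs:
      EGFP: {Ly6G: 0.60}
      double: {MHCII_hi: 0.70, CX3CR1: 0.50}
      EYFP: {CX3CR1: 0.90}
  - condition: MOG.CFA.PTX
    day: 21
    n_cells: {EGFP: 40, EYFP: 150, double: 25, other: 40}
    plaque_count_mean: [0.5, 2.0]
    plaque_channel_mix: {EGFP: 0.40, EYFP: 0.35, double: 0.25}
    flag_probs:
      EGFP: {Ly6G: 0.55}
      double: {MHCII_hi: 0.50, CX3CR1: 0.50}
      EYFP: {CX3CR1: 0.90}
  - condition: CFA.PTX
    day: 14
    n_cells: {EGFP: 30, EYFP: 120, double: 3, other: 30}
    plaque_count_mean: [0.0, 0.0]
    plaque_channel_mix: {EGFP: 1.0}
    flag_probs:
      EGFP: {Ly6G: 0.70}
      double: {MHCII_hi: 0.30, CX3CR1: 0.50}
      EYFP: {CX3CR1: 0.90}
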