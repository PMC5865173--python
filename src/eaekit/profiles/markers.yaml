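# Marker-level intensity model and per-population marker assignments.
#
# Intensities are log10-normal: log10(I) ~ N(level_mean, log_sd).  Level
# means are shared across markers; adjacent levels used as gate boundaries
# are spaced >= 3.3 log_sd so that populations are separable but overlap in
# the tails.  Markers not listed for a population default to "neg".
#
# fp holds probabilities of (EGFP-only, EYFP-only, EGFP+EYFP double)
# expression; origin_prob_donor is the probability of donor (CD45.2)
# bone-marrow origin in chimera samples.

levels:
  neg: 1.0
  dim: 1.9
  int: 2.7
  pos: 3.3
  high: 4.1
log_sd: 0.18

# Number and identity of expected expression levels per channel; channels
# not listed are bi-level (neg/pos).  Used by automatic threshold derivation.
tri_level:
  CD45: [neg, dim, int, high]
  MHCII: [neg, pos, high]

populations:
  Jurkat:
    markers: {hCD3: pos}
    fp: [0.0, 0.0, 0.0]
    origin_prob_donor: 0.0
  Bc:
    markers: {CD45: high, CD19: pos, MHCII: pos, CD45_2: pos}
    fp: [0.0, 0.20, 0.0]      # CD11c-EYFP expressed alone in ~20% of B cells
    origin_prob_donor: 1.0
  NKc:
    markers: {CD45: high, CD161: pos, CD45_2: pos}
    fp: [0.0, 0.0, 0.0]
    origin_prob_donor: 1.0
  Tc_CD8:
    markers: {CD45: high, TCRb: pos, CD5: pos, CD8a: pos, CD45_2: pos}
    fp: [0.0, 0.0, 0.0]
    origin_prob_donor: 1.0
  Tc_CD4:
    markers: {CD45: high, TCRb: pos, CD5: pos, CD45_2: pos}
    fp: [0.0, 0.0, 0.0]
    origin_prob_donor: 1.0
  Ne:
    markers: {CD45: high, CD11b: pos, Ly6G: pos, Ly6C: int, CD44: pos, CD45_2: pos}
    fp: [0.90, 0.0, 0.005]    # LysM-EGFP labels neutrophils
    origin_prob_donor: 1.0
  Mi_rest:
    markers: {CD45: dim, CD11b: pos, CD64: pos, F4_80: pos, CD45_2: pos}
    fp: [0.0, 0.05, 0.0]
    origin_prob_donor: 0.0    # microglia are exclusively host origin
  Mi_act:
    markers: {CD45: int, CD11b: pos, CD11c: pos, CD64: pos, F4_80: pos,
              MHCII: pos, CD45_2: pos}
    fp: [0.0, 0.95, 0.0]      # activated microglia densely CD11c-EYFP labeled
    origin_prob_donor: 0.0
  cDC1:
    markers: {CD45: high, CD11c: pos, MHCII: high, CD45_2: pos}
    fp: [0.0, 0.50, 0.0]
    origin_prob_donor: 1.0
  cDC2:
    markers: {CD45: high, CD11b: pos, CD11c: pos, MHCII: high, CD45_2: pos}
    fp: [0.0, 0.50, 0.0]
    origin_prob_donor: 1.0
  P1_mono:
    markers: {CD45: high, CD11b: pos, Ly6C: pos, CD64: dim, CD44: pos, CD45_2: pos}
    fp: [0.90, 0.0, 0.005]
    origin_prob_donor: 1.0    # CD44+ R9 cells are exclusively donor derived
  P2_moDC:
    markers: {CD45: high, CD11b: pos, Ly6C: pos, CD64: pos, CD44: pos,
              MHCII: pos, CD11c: dim, CD45_2: pos}
    fp: [0.72, 0.0, 0.18]     # 20% of EGFP+ moDC-P2 co-express EYFP
    origin_prob_donor: 1.0
  P3_moDC:
    markers: {CD45: high, CD11b: pos, CD64: pos, CD44: pos, MHCII: high,
              CD11c: pos, CD45_2: pos}
    fp: [0.63, 0.0, 0.27]     # 30% of EGFP+ moDC-P3 co-express EYFP
    origin_prob_donor: 1.0
  P4_mac:
    markers: {CD45: high, CD11b: pos, CD64: pos, F4_80: pos, CD45_2: pos}
    fp: [0.0, 0.20, 0.0]
    origin_prob_donor: 0.91   # 91% of CD44- macrophages are donor derived
  P5_mac:
    markers: {CD45: high, CD11b: pos, CD64: pos, F4_80: pos, MHCII: high,
              CD45_2: pos}
    fp: [0.0, 0.20, 0.0]
    origin_prob_donor: 0.91
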