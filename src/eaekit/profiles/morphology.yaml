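# Morphology class mixtures per fluorescence channel.
#
# EGFP+ cells: ~80% ameboid, ~20% elongated (bipolar), ~2% ramified;
# EYFP+ cells: 50% ramified.  Printed values are renormalized to sum to 1
# at load time.  Phagocytic inclusions occur in ameboid and ramified cells
# (motile elongated cells are non-phagocytic); EYFP rates are set so the
# channel-wide phagocytic fraction is 15%.

channels:
  EGFP:
    class_fractions: {ameboid: 0.80, elongated: 0.20, ramified: 0.02}
    phagocytic_fraction: {ameboid: 0.02, elongated: 0.0, ramified: 0.02}
  EYFP:
    class_fractions: {ameboid: 0.35, elongated: 0.15, ramified: 0.50}
    phagocytic_fraction: {ameboid: 0.17647, elongated: 0.0, ramified: 0.17647}
mask_size: 96
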