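# Longitudinal intravital-imaging profile: per-day multipliers of the
# pre-induction baseline for each cell channel, axon counts and clinical
# score.  EGFP+ density rises from day 10-11 and peaks at day 13; the
# double-labeled (EGFP+/EYFP+) density peaks at day 17; EYFP+ density
# drifts up slightly; axon counts drop at day 13 and stabilize; clinical
# scores rise from day 10 and plateau (anti-correlated with axon counts).

days: [0, 8, 10, 13, 15, 17, 21, 23]
baseline_per_fov: {EGFP: 8.0, EYFP: 6.0, double: 0.5}
baseline_axons: 120
field_of_view_um: 424
effects:
  EGFP:   {0: 1.0, 8: 1.3, 10: 3.5, 13: 6.0, 15: 4.5, 17: 3.0, 21: 2.0, 23: 1.8}
  double: {0: 1.0, 8: 1.0, 10: 1.2, 13: 2.0, 15: 4.0, 17: 8.0, 21: 3.0, 23: 2.0}
  EYFP:   {0: 1.0, 8: 1.05, 10: 1.1, 13: 1.2, 15: 1.3, 17: 1.5, 21: 1.4, 23: 1.3}
  axon:   {0: 1.0, 8: 1.0, 10: 0.97, 13: 0.72, 15: 0.68, 17: 0.65, 21: 0.65, 23: 0.64}
score:    {0: 0.0, 8: 0.0, 10: 0.5, 13: 2.0, 15: 2.5, 17: 3.0, 21: 3.0, 23: 2.8}
mouse_log_sd: 0.25     # log-normal per-mouse random effect (per channel)
noise_log_sd: 0.15     # log-normal measurement noise on densities
score_sd: 0.25
score_max: 5.0
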