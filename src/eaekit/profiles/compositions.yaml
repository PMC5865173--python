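# Population composition of CD45+ events per (condition, tissue, day).
#
# Headline fractions encode the reported structure of the infiltrate:
# a ~70:30 neutrophil:monocyte split among EGFP+ cells, moDCs absent early
# and appearing at day 13, a 70:30 P3:P2 moDC maturation split by day 17
# with moDCs at 24-31% of all immune cells and exceeding microglia 3-4x,
# EYFP+ cells dominated (>90%) by microglia at day 17, and low macrophage
# (P4/P5) fractions throughout with P5 > P4 at day 17.  Minor-population
# fractions (NK, B, cDC1/2) and control/blood compositions are qualitative
# approximations (approx: true), filled per the stated dominance ordering.

compositions:
  - {condition: MOG.CFA.PTX, tissue: SC, day: 8, approx: true,
     fractions: {Ne: 0.42, P1_mono: 0.18, Mi_rest: 0.15, Mi_act: 0.03,
                 Tc_CD4: 0.09, Tc_CD8: 0.04, Bc: 0.02, NKc: 0.015,
                 cDC1: 0.005, cDC2: 0.01, P4_mac: 0.02, P5_mac: 0.02}}
  - {condition: MOG.CFA.PTX, tissue: SC, day: 13, approx: true,
     fractions: {Ne: 0.35, P1_mono: 0.14, P2_moDC: 0.09, P3_moDC: 0.11,
                 Mi_rest: 0.04, Mi_act: 0.05, Tc_CD4: 0.10, Tc_CD8: 0.04,
                 Bc: 0.02, NKc: 0.01, cDC1: 0.004, cDC2: 0.006,
                 P4_mac: 0.015, P5_mac: 0.025}}
  - {condition: MOG.CFA.PTX, tissue: SC, day: 17, approx: true,
     fractions: {Ne: 0.30, P1_mono: 0.10, P2_moDC: 0.09, P3_moDC: 0.21,
                 Mi_rest: 0.02, Mi_act: 0.06, Tc_CD4: 0.149, Tc_CD8: 0.04,
                 Bc: 0.005, NKc: 0.008, cDC1: 0.001, cDC2: 0.002,
                 P4_mac: 0.006, P5_mac: 0.009}}
  - {condition: PBS, tissue: SC, day: 8, approx: true,
     fractions: &pbs_sc {Ne: 0.44, P1_mono: 0.18, Mi_rest: 0.25, Mi_act: 0.01,
                 Tc_CD4: 0.04, Tc_CD8: 0.02, Bc: 0.02, NKc: 0.01,
                 cDC1: 0.002, cDC2: 0.003, P4_mac: 0.015, P5_mac: 0.01}}
  - {condition: PBS, tissue: SC, day: 13, approx: true, fractions: *pbs_sc}
  - {condition: PBS, tissue: SC, day: 17, approx: true, fractions: *pbs_sc}
  - {condition: CFA.PTX, tissue: SC, day: 8, approx: true,
     fractions: &cfa_sc {Ne: 0.46, P1_mono: 0.19, Mi_rest: 0.21, Mi_act: 0.01,
                 Tc_CD4: 0.04, Tc_CD8: 0.02, Bc: 0.02, NKc: 0.01,
                 cDC1: 0.002, cDC2: 0.003, P4_mac: 0.015, P5_mac: 0.02}}
  - {condition: CFA.PTX, tissue: SC, day: 13, approx: true, fractions: *cfa_sc}
  - {condition: CFA.PTX, tissue: SC, day: 17, approx: true, fractions: *cfa_sc}
  - {condition: MOG.CFA.PTX, tissue: brain, day: 17, approx: true,
     fractions: {Mi_rest: 0.10, Mi_act: 0.10, Ne: 0.15, P1_mono: 0.08,
                 P2_moDC: 0.08, P3_moDC: 0.16, Tc_CD4: 0.15, Tc_CD8: 0.06,
                 Bc: 0.03, NKc: 0.02, cDC1: 0.01, cDC2: 0.02,
                 P4_mac: 0.02, P5_mac: 0.02}}
  # disease-onset brain sample used for bone-marrow chimera validation
  - {condition: MOG.CFA.PTX, tissue: brain, day: 15, approx: true,
     fractions: {Mi_rest: 0.30, Mi_act: 0.10, Ne: 0.11, P1_mono: 0.10,
                 P2_moDC: 0.06, P3_moDC: 0.08, Tc_CD4: 0.12, Tc_CD8: 0.04,
                 Bc: 0.02, NKc: 0.01, cDC1: 0.005, cDC2: 0.005,
                 P4_mac: 0.02, P5_mac: 0.03}}
  - {condition: MOG.CFA.PTX, tissue: blood, day: 8, approx: true,
     fractions: {Ne: 0.35, P1_mono: 0.25, Tc_CD4: 0.20, Tc_CD8: 0.08,
                 Bc: 0.07, NKc: 0.03, cDC1: 0.005, cDC2: 0.005,
                 P4_mac: 0.005, P5_mac: 0.005}}
  - {condition: MOG.CFA.PTX, tissue: blood, day: 13, approx: true,
     fractions: &mog_blood_late {Ne: 0.30, P1_mono: 0.12, Tc_CD4: 0.28,
                 Tc_CD8: 0.10, Bc: 0.12, NKc: 0.04, cDC1: 0.01, cDC2: 0.01,
                 P4_mac: 0.01, P5_mac: 0.01}}
  - {condition: MOG.CFA.PTX, tissue: blood, day: 17, approx: true,
     fractions: *mog_blood_late}
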