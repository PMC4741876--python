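# Default per-class, per-epoch fate rates for 70-hour observation windows.
#
# Epochs: day14 governs [day 14, 30), day30 governs [day 30, 49), day49plus thereafter.
# Fate probabilities (p_death + p_divide + p_rest = 1) are per 70-h window.
# Conditional on division: p_multi is the probability of a multi-daughter
# (depolyploidizing, >=3 daughters) division; multi_daughter_dist gives the
# daughter-count distribution; p_fusion_per_daughter is the marginal probability
# that a daughter fuses with a sibling immediately after cytokinesis; bud_rate is
# the expected number of budded daughters per depolyploidizing cell per window.
#
# Source flags follow the calibration convention (measured / derived / placeholder).
# Giant-cell anchors: 60% death on day 14; bipolar:multi 25:1 (day 14) and 10:1
# (day >= 49); multi-daughter counts {3: 2/3, 4: 1/3}; ~17% of daughters fuse.
# bud_rate = 3.7 - 10/3 is derived from the average 3.7 total progeny per
# depolyploidizing cell per window.

G:
  day14:
    p_death: 0.60
    p_divide: 0.15
    p_rest: 0.25
    p_multi: 0.038461538461538464     # 1/26  (25:1 bipolar:multi)
    multi_daughter_dist: {3: 0.6666666666666666, 4: 0.3333333333333333}
    p_fusion_per_daughter: 0.17
    bud_rate: 0.36666666666666666     # 3.7 - 10/3
    source:
      p_death: measured
      p_divide: placeholder
      p_rest: placeholder
      p_multi: measured
      multi_daughter_dist: measured
      p_fusion_per_daughter: measured
      bud_rate: derived
  day30:
    p_death: 0.20
    p_divide: 0.35
    p_rest: 0.45
    p_multi: 0.05555555555555555      # 1/18, between the day-14 and day-49 anchors
    multi_daughter_dist: {3: 0.6666666666666666, 4: 0.3333333333333333}
    p_fusion_per_daughter: 0.17
    bud_rate: 0.36666666666666666
    source:
      p_death: "placeholder (death clearly decreased, divisions exceed death)"
      p_divide: placeholder
      p_rest: placeholder
      p_multi: placeholder
      multi_daughter_dist: measured
      p_fusion_per_daughter: measured
      bud_rate: derived
  day49plus:
    p_death: 0.15
    p_divide: 0.40
    p_rest: 0.45
    p_multi: 0.09090909090909091      # 1/11  (10:1 bipolar:multi)
    multi_daughter_dist: {3: 0.6666666666666666, 4: 0.3333333333333333}
    p_fusion_per_daughter: 0.17
    bud_rate: 0.36666666666666666
    source:
      p_death: placeholder
      p_divide: placeholder
      p_rest: placeholder
      p_multi: measured
      multi_daughter_dist: measured
      p_fusion_per_daughter: measured
      bud_rate: derived

S:
  day14:
    p_death: 0.25
    p_divide: 0.25
    p_rest: 0.50
    p_multi: 0.0
    source:
      p_death: "placeholder (division and death rates similar on day 14)"
      p_divide: placeholder
      p_rest: placeholder
      p_multi: "derived (small cells do not depolyploidize)"
  day30:
    p_death: 0.20
    p_divide: 0.30
    p_rest: 0.50
    p_multi: 0.0
    source: {p_death: placeholder, p_divide: placeholder, p_rest: placeholder, p_multi: derived}
  day49plus:
    p_death: 0.15
    p_divide: 0.40
    p_rest: 0.45
    p_multi: 0.0
    source: {p_death: placeholder, p_divide: placeholder, p_rest: placeholder, p_multi: derived}

M:
  day14:
    p_death: 0.25
    p_divide: 0.25
    p_rest: 0.50
    p_multi: 0.0
    source:
      p_death: placeholder
      p_divide: placeholder
      p_rest: placeholder
      p_multi: "placeholder (no depolyploidizing events seen in day-14/30 medium cells)"
  day30:
    p_death: 0.20
    p_divide: 0.30
    p_rest: 0.50
    p_multi: 0.0
    source: {p_death: placeholder, p_divide: placeholder, p_rest: placeholder, p_multi: placeholder}
  day49plus:
    p_death: 0.15
    p_divide: 0.35
    p_rest: 0.50
    p_multi: 0.02
    multi_daughter_dist: {3: 0.6666666666666666, 4: 0.3333333333333333}
    p_fusion_per_daughter: 0.0
    bud_rate: 0.0
    source:
      p_death: placeholder
      p_divide: placeholder
      p_rest: placeholder
      p_multi: "placeholder (medium-cell multi-daughter divisions appear only at later stages)"
      multi_daughter_dist: placeholder
      p_fusion_per_daughter: placeholder
      bud_rate: placeholder
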