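# Default calibration for the synthetic SKOV3 carboplatin (CPT) time course.
#
# Source flags per field:
#   measured    — a printed measurement from the underlying experiments
#   derived     — an arithmetic consequence of measured values
#   placeholder — a plausible default not anchored to a printed number; override freely
#
# Areas are attached-cell areas in um^2, DNA content in C units (2C = diploid G1).
# Per-class area components are log-normal; where a timepoint carries a
# target_median_um2 and anchor_class, the anchor component's median is solved at
# load time so that the weighted mixture median equals the target exactly.

defaults:
  class_sigmas: {S: 0.16, M: 0.10, G: 0.33}      # log-scale spreads; chosen so <0.1% of
                                                 # each component crosses a size threshold
  class_medians_um2: {S: 1700.0, M: 4243.0, G: 16000.0}
  nuclear_ratio: 0.25                            # nuclear/cell area scale; thresholds scale with it
  dna_components:                                # <1% of each component crosses a C-band boundary
    para: {center_C: 2.5, sigma: 0.14}
    poly: {center_C: 5.657, sigma: 0.12}
    high: {center_C: 12.0, sigma: 0.12}

timepoints:
  d0:
    days: 0
    size_weights: {S: 0.96, M: 0.03, G: 0.01}
    target_median_um2: 1700.0
    anchor_class: S
    nuclear_weights: {S: 0.96, M: 0.03, G: 0.01}
    dna_weights: {para: 0.93, poly: 0.067, high: 0.003}   # 7% >4C, 0.3% >8C untreated
    markers: {p21: 0.02, BrdU: 0.50, beta_gal: 0.01, OCT4: 0.12, IL1B: 0.05, SMA: 0.02}
    source:
      size_weights: placeholder
      target_median_um2: measured
      nuclear_weights: placeholder
      dna_weights: measured
      markers: "OCT4 measured (12% positive untreated); others placeholder"

  d8:
    days: 8
    size_weights: {S: 0.75, M: 0.15, G: 0.10}
    nuclear_weights: {S: 0.75, M: 0.15, G: 0.10}
    dna_weights: {para: 0.80, poly: 0.18, high: 0.02}
    markers: {p21: 0.15, BrdU: 0.10, beta_gal: 0.02, OCT4: 0.20, IL1B: 0.15, SMA: 0.03}
    source:
      size_weights: placeholder
      nuclear_weights: placeholder
      dna_weights: placeholder
      markers: "placeholder (p21 strongly induced by day 8, BrdU transiently depressed)"

  d10:
    days: 10
    size_weights: {S: 0.55, M: 0.20, G: 0.25}
    nuclear_weights: {S: 0.55, M: 0.20, G: 0.25}
    dna_weights: {para: 0.75, poly: 0.22, high: 0.03}
    markers: {p21: 0.18, BrdU: 0.15, beta_gal: 0.03, OCT4: 0.30, IL1B: 0.25, SMA: 0.04}
    source:
      size_weights: "placeholder (giant surge occurs between day 10 and 14)"
      nuclear_weights: placeholder
      dna_weights: placeholder
      markers: placeholder

  d14:
    days: 14
    size_weights: {S: 0.08, M: 0.16, G: 0.76}
    target_median_um2: 16000.0
    anchor_class: G
    nuclear_weights: {S: 0.02, M: 0.04, G: 0.94}
    dna_weights: {para: 0.67, poly: 0.265, high: 0.065}   # 33% >4C, 6.5% >8C at peak
    markers: {beta_gal: 0.05, OCT4: 0.55, IL1B: 0.50, SMA: 0.10}
    # p21 x BrdU joint: pp = p21+BrdU+, pm = p21+BrdU-, mp = p21-BrdU+, mm = both negative.
    # The p21 marginal (22%) is measured; the split of the quadrants is a placeholder kept
    # inside the reported 27-47% range of cycling (p21-BrdU+) cells.
    p21_brdu_quadrants: {pp: 0.12, pm: 0.10, mp: 0.37, mm: 0.41}
    source:
      size_weights: measured
      target_median_um2: measured
      nuclear_weights: measured
      dna_weights: measured
      markers: "beta_gal (~5%) and OCT4 (55%) measured; IL1B, SMA placeholder"
      p21_brdu_quadrants: "p21 marginal (22%) measured; quadrant split placeholder"

  d28:
    days: 28
    size_weights: {S: 0.35, M: 0.30, G: 0.35}
    nuclear_weights: {S: 0.35, M: 0.30, G: 0.35}
    dna_weights: {para: 0.70, poly: 0.24, high: 0.06}
    markers: {p21: 0.05, BrdU: 0.35, beta_gal: 0.04, OCT4: 0.58, IL1B: 0.40, SMA: 0.15}
    source:
      size_weights: "derived qualitatively (small and giant cells at similar numbers by day 28)"
      nuclear_weights: placeholder
      dna_weights: placeholder
      markers: placeholder

  d30:
    days: 30
    size_weights: {S: 0.40, M: 0.30, G: 0.30}
    nuclear_weights: {S: 0.40, M: 0.30, G: 0.30}
    dna_weights: {para: 0.70, poly: 0.24, high: 0.06}
    markers: {beta_gal: 0.05, OCT4: 0.60, IL1B: 0.35, SMA: 0.20}
    p21_brdu_quadrants: {pp: 0.005, pm: 0.005, mp: 0.45, mm: 0.54}
    source:
      size_weights: placeholder
      nuclear_weights: placeholder
      dna_weights: placeholder
      markers: placeholder
      p21_brdu_quadrants: "p21 marginal (1%) measured; quadrant split placeholder"

  w7:
    days: 49
    size_weights: {S: 0.60, M: 0.25, G: 0.15}
    nuclear_weights: {S: 0.60, M: 0.25, G: 0.15}
    dna_weights: {para: 0.75, poly: 0.19, high: 0.06}
    markers: {p21: 0.02, BrdU: 0.45, beta_gal: 0.20, OCT4: 0.70, IL1B: 0.35, SMA: 0.45}
    source:
      size_weights: placeholder
      nuclear_weights: placeholder
      dna_weights: placeholder
      markers: placeholder

  21w:
    days: 147
    size_weights: {S: 0.90, M: 0.08, G: 0.02}
    target_median_um2: 2000.0
    anchor_class: S
    class_sigmas: {S: 0.13}      # tighter small-cell spread keeps the component inside <3000
    nuclear_weights: {S: 0.90, M: 0.08, G: 0.02}
    dna_weights: {para: 0.835, poly: 0.1325, high: 0.0325}  # >4C and >8C halved vs day 14
    markers: {beta_gal: 0.60, OCT4: 0.84, IL1B: 0.30, SMA: 0.80}
    p21_brdu_quadrants: {pp: 0.015, pm: 0.015, mp: 0.55, mm: 0.42}
    source:
      size_weights: placeholder
      target_median_um2: measured
      nuclear_weights: placeholder
      dna_weights: "derived (polyploid fractions halved relative to day 14)"
      markers: "OCT4 (84%) measured; beta_gal strongly increased but unquantified; rest placeholder"
      p21_brdu_quadrants: "pm (p21+BrdU- = 1.5%) measured; remainder placeholder"
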