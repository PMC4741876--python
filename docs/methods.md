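# Methods

`ploidysim` models the population dynamics of ovarian carcinoma cells under
sustained carboplatin exposure: the transient dominance of polyploid giant
cells, their fates over 70-hour observation windows (death, bipolar division,
depolyploidizing multi-daughter division, sibling fusion, budding, resting),
and the ancestry of the small, proliferative, drug-resistant cells that
eventually take over the culture.  This note records the model, its
parameters, the numerical choices, and what the synthetic data do and do not
represent.

## Synthetic per-cell measurements

Each timepoint of the treatment time course (labels `d0, d8, d10, d14, d28,
d30, w7, 21w`; a closed registry — intermediate times are not interpolated)
carries:

- **Size-class weights** over small (S, < 3,000 µm²), medium (M,
  3,000–6,000 µm²) and giant (G, > 6,000 µm²) attached-cell areas. The day-14
  split is 8/16/76%.
- **Per-class area components**, log-normal with class-specific medians and
  log-scale sigmas (defaults S: 0.16, M: 0.10, G: 0.33). Right skew matches
  the observed dot plots; only medians and class fractions are calibrated, so
  the component shape is a modeling choice. Sigmas are chosen so that less
  than 0.1% of each component's mass crosses a class threshold; the generated
  latent class labels therefore agree with the area classifier on ≥ 99.9% of
  cells, which is tested.
- **Anchored medians.** Where an overall median area is calibrated (day 0:
  1,700 µm²; day 14: 16,000 µm²; 21 weeks: 2,000 µm²), the dominant
  ("anchor") component's median is solved in closed form at load time so the
  weighted mixture median equals the target exactly:
  `m_a = T · exp(−Φ⁻¹(q)·σ_a)` with
  `q = (1/2 − Σ_{c≠a} w_c F_c(T)) / w_a`. At 21 weeks the small-cell sigma is
  tightened to 0.13 because the anchored median (~1,960 µm²) sits closer to
  the 3,000 µm² threshold.
- **Nuclear areas** reuse the same mixture scaled by a configurable
  nuclear/cell area ratio (default 0.25), with separate nuclear-class weights
  (day 14: 2/4/94%). Absolute nuclear thresholds are not calibrated, so
  nuclear classification scales the cell thresholds by the same ratio.
- **DNA content** is a three-band log-normal mixture in C units: para-diploid
  (≤ 4C, center 2.5C), polyploid (4–8C, center 5.66C) and high-polyploid
  (> 8C, center 12C), with sigmas (0.14/0.12/0.12) chosen so < 1% of each
  component crosses a band boundary. Band weights: day 0 — 93/6.7/0.3%;
  day 14 — 67/26.5/6.5%; 21 weeks — the polyploid fractions halved relative
  to day 14. The para band is a single component; G1/G2 peak structure within
  the band is deliberately not modeled (nothing downstream depends on it).
- **Markers** (p21, BrdU, β-gal, OCT4, IL-1β, SMA) are Bernoulli draws,
  independent of cell size and of each other — except p21 and BrdU, which are
  drawn jointly from a 2×2 quadrant table where the joint structure is
  calibrated (day 14, day 30, 21 weeks). Calibrated marginals: p21 22% →
  1% (day 14 → 30), OCT4 12% → 55% → 84% (day 0 → 14 → 21 weeks), β-gal ~5%
  at day 14, and p21⁺BrdU⁻ 1.5% at 21 weeks. The day-14 quadrant split keeps
  cycling (p21⁻BrdU⁺) cells at 37%, inside the reported 27–47% range.

Every value in the packaged calibration carries a `source` flag: `measured`
(a printed measurement), `derived` (arithmetic consequence of measured
values) or `placeholder` (chosen once as a plausible default — the d8/d10/
d28/w7 size and marker values, and all nuclear weights except day 14, are in
this category and should not be treated as data).

What passing calibration tests show: the generator's marginals and medians
match the configured values. What they do not show: real flow-cytometry or
image-analysis data have instrument noise, debris, doublets, cell-cycle
sub-structure and size–marker correlations that the generator deliberately
omits (only the p21×BrdU joint is modeled).

## Fate model

The unit of observation is the 70-hour window. Per (size class, epoch):

- fate probabilities `p_death + p_divide + p_rest = 1`;
- conditional on division, `p_multi` is the probability of a multi-daughter
  (depolyploidizing) division; the daughter count is 3 with probability 2/3
  and 4 with probability 1/3 (giving E[K] = 10/3);
- each daughter may fuse with a sibling immediately after cytokinesis, with
  per-daughter marginal probability `p_fusion_per_daughter` (default 0.17
  for giant cells). Fusion is drawn per sibling pair; for odd brood sizes
  the pair-level probability is scaled by `k/(2⌊k/2⌋)` so the per-daughter
  marginal is exact for every brood size and the estimator
  `2·pairs/daughters` is unbiased;
- `bud_rate` is the expected number of budded daughters per depolyploidizing
  cell per window, default `3.7 − 10/3 ≈ 0.367`, back-computed so that the
  average total progeny per depolyploidizing cell (multi-daughter mitosis
  plus budding) equals 3.7. Budding is attached to multi-daughter division
  events (a Poisson draw per event), matching the observed sequence of
  budding followed by multi-daughter division;
- multinucleation (< 2% of giant mitoses) is treated as a no-op: it neither
  changes daughter counts nor classes. It is rare and under-characterized.

Giant-cell anchors: 60% death at day 14; bipolar:multi ratios 25:1 (day 14)
and 10:1 (day ≥ 49), i.e. `p_multi = 1/26` and `1/11`, with `1/18` as an
interim day-30 placeholder. Small- and medium-cell fate fractions are
placeholders consistent with the qualitative observations (division ≈ death
initially, later net growth); medium cells have `p_multi = 0` before day 49
because no depolyploidizing events were observed in them earlier (an opt-in
flag re-enables it for sensitivity analysis).

`estimate_rates` recovers all parameters as empirical fractions with
Clopper–Pearson exact 95% intervals (several cells have few events; exact
intervals are conservative but honest at these sizes) and reports a
chi-squared test of fate homogeneity across epochs within each class.
`expected_progeny` exposes both the depolyploidizing-conditional expectation
(Σ k·P(k) + bud rate = 3.7 under the defaults) and the per-division
expectation mixing bipolar and multi-daughter outcomes, because the printed
3.7 is ambiguous between the two readings; the conditional reading is the
default as it reproduces the printed arithmetic exactly.

## Population simulator

Discrete time, default step = one 70-hour window (the observation unit).
Epochs are piecewise constant: day-14 rates govern [14, 30), day-30 rates
[30, 49), day-49+ rates thereafter; linear interpolation between the epoch
anchor times is an opt-in flag. Per step and cell: death removes; resting
persists; bipolar division yields two same-class daughters; multi-daughter
division yields 3–4 daughters of the small class (depolyploidization;
configurable to M); buds add small daughters; each daughter may fuse with a
sibling, and a fused pair merges into one cell promoted one class (S→M,
M→G, G→G). Fusion never crosses lineages.

Steps shorter than a window rescale the categorical fate probabilities by a
competing-risk conversion: the no-event probability scales as `p_rest^f`
(f = step/window) and the event mass splits proportionally between death and
division. This composes exactly under step halving — the distribution of a
cell's *first* event over a full window is invariant — which is tested.
Within-window daughter re-division is thereby excluded at the default step
and becomes possible at finer steps; this is the usual discretization
trade-off and the reason the default step equals the observation window.

Two execution modes share the same event semantics: a count-based sampler
(multinomial/binomial/Poisson draws per class; fast, used for large cohorts)
and an agent-based sampler that records every cell in a `LineageForest`
(nodes with birth/end times and parent links; fusion products carry two
parents). A deterministic mean-field companion propagates expected counts
with the per-step expectation matrix

    A[c,c]            += p_rest + p_divide·(1−p_multi)·2·(1−p_fus)
    A[promote(c),c]   += p_divide·(1−p_multi)·p_fus
    A[S,c]            += p_divide·p_multi·(E[K]·(1−p_fus) + bud_rate)
    A[M,c]            += p_divide·p_multi·E[K]·p_fus/2

and is used as an oracle: stochastic replicate means must match it within
Monte-Carlo error, and with fusion, budding and multi-daughter division
disabled the model reduces to independent per-class binary branching with
mean growth factor `p_rest + 2·p_divide`.

Ancestry attribution assigns each final-time cell one unit of weight and
splits it equally along parent links (½ per parent at fusion nodes) back to
the founder generation — the cells alive at the reference time (default
day 14). The dynamic program over the chronologically ordered forest equals
exhaustive path enumeration (tested against a brute-force oracle on small
forests). Weights sum to exactly 1 per final cell, so the reported
founder-class fractions partition unity.

Endoreduplication (the smaller→giant conversion that drives the day-10→14
giant surge) is not simulated: the default window starts at day 14, after
the surge. Space, drug pharmacokinetics, explicit DNA content and
EMT/secretory state are likewise outside the simulator's scope — ploidy is
abstracted by size class.

## Default contribution run and problem sizes

The packaged default run starts at day 14 with 1,000 cells split 8/16/76%
(S/M/G), steps in 70-hour windows to day ~57.75 (the last step boundary
before day 60), runs 100 lineage-tracked replicates (replicate seeds are
spawned from the root seed via numpy's `SeedSequence`, a collision-free
deterministic derivation), and reports the founder-class composition of the
final small-cell pool with replicate mean ± sd alongside the mean-field
trajectory. A population of this size keeps exhaustive lineage tracking
cheap (well under a minute for the full analysis) while leaving Monte-Carlo
errors on the reported fractions at a few percent. Under the default rates
the giant pool declines steeply from day 14, the small pool stays within a
factor of two through day 29, and both small and giant founders contribute
substantially to the final small-cell pool (giant founders typically ~20–30%
directly, more if their medium-cell descendants are credited to them).

## Numerical and degenerate-input conventions

- Boundary conventions: 3,000 and 6,000 µm² belong to the medium class; 4C
  and 8C belong to the lower ploidy class (matching the printed interval
  notation). Medians use the midpoint convention for even counts.
- All weight/probability sets over a partition must sum to 1 within 1e-9;
  violations are configuration errors naming the offending field.
- Degenerate inputs: empty cohorts are errors for `summarize` and
  `estimate_rates`; `n = 0` generator calls return empty tables; an
  all-resting track set yields `p_rest = 1` with division-conditional fields
  flagged undefined rather than zero; `division_ratio` reports infinity when
  no multi-daughter divisions occur.
- Every generator and simulation entry point is a pure function of
  `(seed, parameters)`; identical calls produce bitwise-identical tables.
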