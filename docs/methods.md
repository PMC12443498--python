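# Methods

## The estimator

The pipeline models presence/pseudoabsence data with a committee of
bagged-decision-tree (random forest) runs. Each run draws a fresh
stratified 80/20 train/test partition (per class, round-half-up of 80%
to train: 84 + 84 sites give 67 + 67 training and 17 + 17 test sites),
fits 500 trees with √p candidate features per split and unlimited depth,
and is scored on its held-out 20% by:

- **TSS** `= sensitivity(θ) + specificity(θ) − 1`, maximized over the
  cutoff grid θ ∈ {0.00, 0.01, …, 1.00} with prediction positive iff
  score ≥ θ. Ties take the smallest maximizing cutoff. Note this grid
  rule means the reported cutoff is the *left edge* of the maximizing
  interval, which can sit well below the largest maximizing cutoff.
- **AUC**, the rank-sum (Mann–Whitney) statistic with ties counted ½.

Runs with TSS ≥ 0.7 (inclusive) enter the committee. Each selected run
predicts on every river cell with complete environmental data, is
binarized at its own TSS-optimal cutoff, and the committee average EMca
is the mean of the binary votes — exactly k + 1 possible values
{0, 1/k, …, 1} for k selected runs. Binarize-then-average (rather than
averaging probabilities) is what "committee averaging" names; the
per-model TSS-optimal cutoff is the standard choice and a common fixed
cutoff would be the config-exposed alternative.

Ten runs is the default repetition count (enough to give EMca a 0.1 vote
granularity and stable medians; configurable). No prevalence weighting
is applied anywhere because pseudoabsences are drawn with equal count to
presences by construction.

**Variable importance** is permutational: 1 − Pearson r between a run's
reference predictions and its predictions after shuffling one variable's
column, averaged over 3 shuffles and all runs, clipped to [0, 1]. If
shuffling leaves predictions bit-identical (variable unused by every
tree) or either prediction vector is constant, the importance is 0
exactly. **Response curves** are evaluation-strip marginals: one
variable sweeps its observed range on a 100-point grid while the others
sit at their site medians; the ensemble curve is the EMca vote fraction
along the strip. The **high-probability envelope** reports min/q25/q75/
max of each variable over cells with EMca strictly above 0.9 — the
realized environmental niche of the model's top habitat.

## Occurrence curation

Filters run in a fixed order so every dropped record carries exactly one
primary reason: coordinate uncertainty strictly greater than 1000 m,
then event year before 1990, then reservoir/dam waterbody. Records
*missing* uncertainty or date are kept — literature records rarely carry
GBIF-style metadata, and only stated violations count. Early-life
classification accepts documented spawning/nursing evidence, membership
in a spawning-river registry, or Strahler order ≤ 4 at the record's
cell; when the cell carries no order the nearest river cell within a
500 m pull supplies it (taking the maximum order over the radius is the
config-exposed alternative; the two rarely differ on dendritic
networks). Snapping moves records to the nearest river cell with
complete environmental data within 500 m, Euclidean on the equal-area
grid, ties broken to the lexicographically smallest (row, col). Grid
sampling keeps one record per cell by smallest uncertainty, then
earliest date, then smallest source id — a total order, so curation is
fully deterministic. Pseudoabsences are sampled uniformly without
replacement from river cells with environmental data, excluding presence
cells, one per presence, in a single set.

## The synthetic riverscape

The generator manufactures the study conditions; its defaults are the
package's reference study and are not tuned per run.

**Network.** Tributaries grow as persistent-heading meandering
self-avoiding walks from headwater sources toward a random grid-edge
outlet, joining the first river cell they touch, which yields a
downstream-directed tree by construction. The default scene is a
256 × 256 grid of 0.45 km cells (≈15 arc-sec at the equator) with 24
sources — enough confluences for Strahler orders up to 4 and main-stem
flow lengths of several hundred km, so the full extent of the planted
flow-length envelope (support 21–210 km) is realized on the network.
Order-1 tributaries feeding reaches above order 2 are pruned before the
environmental stack is laid down. The grid is an abstract equal-area
Cartesian plane in km; geodesic area computation is out of scope, which
keeps area accounting exact.

**Environmental layers** (defined only on river cells, each confined to
the published range of its real-world counterpart):

- `hyd` is computed exactly as the along-network distance to the
  furthest upstream source (orthogonal steps 0.45 km, diagonal steps
  0.45·√2 km).
- `sgr` is the exponential of an Ornstein–Uhlenbeck process propagated
  downstream along the network (stationary median 600 dm/km, log-sd 0.8,
  correlation length 15 km; at confluences the main stem continues the
  process). Gradients are therefore locally smooth — suitable reaches
  form contiguous stretches rather than salt-and-pepper cells — but
  carry no systematic trend with flow length, so the flow-length
  envelope can be recovered without confounding. The stationary median
  sits well above the species' preferred 120–270 dm/km, making suitable
  habitat scarce (typically < 10% of river cells), which reproduces the
  strong presence/background contrast characteristic of early-life
  habitat studies (held-out AUC near 1).
- Elevation integrates `sgr` upstream from each outlet, hence decreases
  monotonically downstream; `bio10` declines with normalized elevation
  (slope −5 °C over the elevation range) plus a smooth random field and
  N(0, 0.3 °C) noise; `bio16` is a smooth random field; `hft` is a sum
  of clustered Gaussian hotspots. `hft` and `bio16` never enter the true
  suitability and act as negative controls for importance testing.

**Truth.** True suitability is the product of trapezoid memberships —
`hyd` (21 | 63 … 147 | 210 km), `sgr` (40 | 120 … 270 | 320 dm/km),
`bio10` (25.5 | 26.9 … 28.7 | 29.7 °C) — 1 on the plateau, 0 outside the
support, linear on the ramps. Trapezoids (not Gaussians) keep the
high-suitability region's bounds analytically known.

**Occurrences.** 250 records by default: presences drawn from river
cells with probability proportional to true suitability, in-cell jitter
of ±0.2 cell so each record stays nearest its source cell. Four
contamination classes at 5% each (uncertainty 1001–5000 m, event year
1950–1989, reservoir/dam waterbody, displacement beyond the 500 m snap
radius) are assigned to disjoint record subsets and recorded as hidden
ground-truth labels the pipeline never reads; tests assert the curation
survivors equal the clean set exactly. About 30% of records carry
documented life-stage evidence; the rest rely on the Strahler rule.
Expected clean records ≈ 200, collapsing to ≈ 130–150 unique presence
cells after grid sampling.

**Context.** Protected areas are random rectangles accreted around river
cells until they cover the target fraction (default 10%) of river cells,
labeled by the region strip of their center; region polygons are three
vertical strips; river polygons are the union of river cell footprints.

What the generator does *not* emulate: hydrologically realistic flow
accumulation and discharge, climate downscaling, real-coordinate
reprojection, spatial sampling bias across sources, and detection error.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that the estimator recovers a known niche under clean
sampling assumptions — not that any real species' niche would be
recovered from an uncontrolled occurrence compilation.

## Priority areas and accounting

EMca is thresholded strictly above 0.9; connected components under
8-adjacency with **more than 10 cells** (≥ 11, read strictly per the
rule's wording; config-exposed) become clumps, with ids assigned in
raster-scan order of each component's first cell. Clumps are clipped to
river polygons by cell-center membership; a clump losing every cell is
dropped and logged rather than silently vanishing — the model can flag
habitat where no river polygon exists to receive it. Inside/outside
protection is decided by cell-center-in-polygon against the *union* of
protected polygons (overlaps between protected-area sources are unioned
before the test, so nothing is double-counted), which keeps
`inside + outside = total` exact to machine precision. Cells outside
every region polygon are tallied under an explicit "unassigned" row.

## Habitat assessment

Water-quality status is inclusive-bound: lo ≤ v ≤ hi is "within".
Defaults: temperature 13–30 °C and dissolved oxygen 6.4–11 mg/L (both
from the species literature for breeding grounds); pH 7.0–9.0 is an
assumption encoding the species' documented alkaline preference and is
tagged as such; conductivity and TDS have no numeric literature bounds
and stay "unassessed" unless the user supplies bounds. The packaged
example readings and stressor observations are synthetic stand-ins (see
their filenames) spanning published field ranges. Stressor tallies use
the five standard categories; the modal category lists all ties.

## Numerical and reproducibility choices

- One master seed; per-stage seeds are spawned from it by
  `numpy.random.SeedSequence` under fixed names (network, env,
  occurrences, pseudoabsence, modeling, context, importance). No stage
  shares a stream; no hidden global randomness. All generators are
  bit-reproducible for a fixed seed, and a rerun with the same config
  reproduces every CSV byte for byte.
- Fitted classifiers are never persisted; the ensemble stage refits them
  deterministically from the logged seed when run standalone. Every
  artifact is a text file (ASCII grid, GeoJSON, CSV, YAML).
- The correlation gate uses strict inequality at |r| = 0.75; "ecological
  relevance" is operationalized as a caller-supplied priority order and
  the greedy scan is documented in the selection audit.
- Envelope-recovery tolerance in the acceptance suite is expressed as
  15% of the trapezoid's support width (per-bound), since relative error
  of a location on a variable axis is ill-defined near zero and the
  trapezoid's width is its natural scale.
- Degenerate inputs fail loudly: zero-variance columns, single-class
  labels, empty model selections, zero-total regions, cyclic networks,
  and infeasible generator settings all raise typed, stage-named errors.

## Problem sizes

The reference study is one 256 × 256 riverscape (~4300 river cells after
pruning), 250 occurrence records, 10 runs of 500 trees, and committee
prediction over all river cells — about 20 s end to end on one CPU. The
oracle comparisons run the metric pair on 200 random vectors of length
≤ 20 and the clump detector on 100 random 50 × 50 grids.

## Known limitations

- The walk-based network generator controls sinuosity only statistically;
  very small grids with many sources can fail feasibility (they raise).
- EMca's > 0.9 rule with k = 10 runs demands unanimity; the recovered
  envelope is therefore slightly conservative (inside the true support),
  which is visible in the worked example.
- Pseudoabsences may land on suitable-but-unsampled cells (by design, as
  in real background sampling), bounding achievable AUC below 1.
- The habitat-assessment envelope treats parameters independently; no
  joint water-quality index is computed.
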