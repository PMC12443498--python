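# riversdm

Ensemble species distribution modeling of **early-life riverine fish
habitat** — spawning and nursing reaches of the endangered golden mahseer
(*Tor putitora*) in Himalayan river networks — packaged as a reusable,
seed-controlled pipeline and exercised end to end on synthetic
riverscapes with known ground truth.

Conservation planning for migratory river fish needs maps of the
low-order tributary reaches used for egg laying and juvenile rearing,
which differ sharply from adult feeding habitat. The pipeline covers the
whole workflow a spatial ecologist would run:

1. **Occurrence curation** — drop records with coordinate uncertainty
   > 1000 m, event dates before 1990, or reservoir/dam waterbodies; keep
   only early-life evidence (documented spawning/nursing, registered
   spawning rivers, or Strahler order ≤ 4 with a 500 m pull); snap to the
   nearest river cell within 500 m; grid-sample to one presence per cell;
   draw pseudoabsences with equal weightage to presences.
2. **Variable screening** — Pearson correlation gate |r| < 0.75 over the
   candidate predictors, greedy in ecological priority order.
3. **Ensemble modeling** — repeated random-forest runs (500 trees each)
   on stratified 80/20 splits, evaluated by held-out TSS and AUC; runs
   with TSS ≥ 0.7 are binarized at their TSS-optimal cutoffs and averaged
   into the committee score

   `EMca(cell) = (1/k) · Σᵢ 1[pᵢ(cell) ≥ θᵢ]`,

   where `TSS(θ) = sensitivity(θ) + specificity(θ) − 1` is maximized over
   the cutoff grid {0.00, 0.01, …, 1.00} and AUC is the rank-sum
   (Mann–Whitney) statistic. Permutation importance is
   `1 − corr(reference predictions, predictions with one variable
   shuffled)`, and response curves use the evaluation-strip convention.
4. **Priority areas** — cells with EMca > 0.9 are clumped under
   8-directional adjacency; clumps with more than 10 cells are clipped to
   river polygons and accounted per region as area inside/outside
   protected-area polygons.
5. **Habitat assessment** — field water-quality readings (pH,
   temperature, conductivity, TDS, dissolved oxygen) checked against the
   species' preference envelope; observed stressors tallied across five
   categories.

The predictors are flow length to the furthest upstream source (`hyd`,
km), human footprint (`hft`), stream gradient (`sgr`, dm/km), mean
temperature of the warmest quarter (`bio10`, °C), and precipitation of
the wettest quarter (`bio16`, mm).

Because the real occurrence compilation and global rasters behind such
studies are not redistributable, the package ships a first-class
**synthetic riverscape generator**: dendritic networks with Strahler
orders, environmental layers confined to published variable ranges, a
known trapezoidal suitability envelope (on `hyd`, `sgr`, `bio10` only —
`hft` and `bio16` are negative controls), contaminated occurrence
samples with hidden ground-truth labels, and protected-area polygons
covering ~10% of river cells. Every downstream stage is therefore
testable against a truth the generator controls.

## Worked example

Run the whole default study (seed 0) from the shell:

```sh
riversdm --seed 0 --outdir runs/demo all
```

or step through the numbered scripts under `analysis/` (they share
`scratch/study/` and copy their summary tables into `results/`):

```sh
cd analysis
python 01_simulate_riverscape.py
python 02_curate_occurrences.py
...
```

The curation script prints the audit trail of the 250 raw records:

```
raw records: 250
  filter: 250 in, 36 dropped {'uncertainty': 12, 'date': 12, 'waterbody': 12}
  classify: 214 in, 6 dropped {'no_order_within_pull': 6}
  snap: 208 in, 6 dropped {'unsnappable': 6}
  grid_sample: 202 in, 70 dropped {'duplicate_cell': 70}
modeling presences: 132 cells (+ 132 pseudoabsences, equal weightage)
survivors match the generator's clean ground truth: True
```

exactly the 48 seeded defects are removed (12 per class; the 12
off-river records fall at the classification or snapping stage), and the
202 clean records collapse to 132 unique presence cells. The ensemble
then reports:

```
10 runs: TSS 0.885-1.000 (median 0.962), AUC 0.938-1.000 (median 0.993)
10 runs selected at TSS >= 0.7

environmental envelope of EMca > 0.9 cells vs the true trapezoids:
  hyd: recovered [23.9 | 55.0 .. 142.4 | 200.0]  true [21.0 | 63.0 .. 147.0 | 210.0]
```

so the committee recovers the planted flow-length envelope (support and
interquartile bounds) to within a few percent of its width, and the
three true driver variables take the top three importance ranks. The
priority stage finds 19.4 km² of high-probability early-life habitat, of
which 78% lies outside protected areas in this synthetic scene:

```
            total_km2  inside_pa_km2  outside_pa_km2
west            5.062          0.000           5.062
central         0.608          0.202           0.405
east           13.770          4.050           9.720
all            19.440          4.252          15.188
```

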