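# trackforest

Statistics for video-based single-cell tracking data, organized around
**pedigree forests**: the trees formed by the cells present at the start of a
time-lapse recording (the roots) and all of their descendants, with division
and death events annotated along the way.

Long-term live-cell imaging of an adherent monolayer — for example tumour
cells filmed for ~94 h at 6-min frames under a toxin exposure — produces two
tables: per-frame cell positions, and per-cell lineage records (parent,
birth/end time, fate). `trackforest` compresses those tables into a small set
of comparable, parameterized summaries:

* **Tree classification** — each tree is `SURVIVING` (≥ 1 member alive at the
  end) or `EXTINCT`, with a `NO_DEATH` flag for surviving trees without any
  death event, the operational proxy for a resistant subpopulation.
* **Growth curves** — the census of cells alive over time, as a percentage of
  the starting count (or aligned at each tree's first division, where curves
  start at exactly 200 %), compressed into the cubic model
  `P3(t) = 100 + a·t + b·t² + c·t³` with the intercept fixed at 100.
* **Smoothed kinematics** — Nadaraya–Watson Gaussian-kernel smoothing of each
  track (bandwidth σ = 15 min), analytic speed, arc ("track") length, and
  centered moving generalized power means `M_p = (mean vᵖ)^(1/p)` of speed
  (default 8-h window; larger p emphasizes the fastest episodes).
* **Sister-cell statistics** — for the two daughters of a root's first
  division: joint distributions of per-subtree descendant counts
  (Gaussian-smoothed count histogram, bandwidth 1.5) and of total subtree
  track lengths (Gaussian KDE with Scott's bandwidth), plus their Pearson
  correlation — positive correlation is a signature of inheritance.
* **Displacement curves** — birth-aligned mean squared displacement
  `c(t) = r(t)·r(t)` and the sibling cross-displacement
  `c₁,₂(t) = r₁(t)·r₂(t)`; `c(t)/t` is flat for memoryless motion, and the
  persistent-random-walk (Fürth) fit `c(t) = 4D(t − P(1 − e^(−t/P)))`
  yields the directional **memory time** P.
* **Proximity events** — maximal intervals in which two concurrently-alive
  cells stay within a distance threshold for ≥ 4 h, ignoring the first 2 h
  after either cell's birth (sisters are trivially adjacent after division).
* **Synthetic recordings** — a branching-process simulator with exact
  Ornstein–Uhlenbeck (persistent random walk) motion, heritable per-lineage
  traits, two death modes, resistant lineages, sister coupling and
  measurement noise, so every statistic above is testable without raw
  microscopy data.

## Data format

Two UTF-8 CSV files. Track table `cell_id,frame,time_h,x,y`, one row per cell
per frame; cell table `cell_id,parent_id,birth_time_h,end_time_h,fate` with
an empty `parent_id` marking a root and `fate` one of `DIVIDED`,
`DEATH_APOPTOTIC`, `DEATH_NECROTIC`, `ALIVE_AT_END`, `LOST`. Times are hours
since the recording start; coordinates use the image convention (x rightward,
y downward) in the unit recorded in the metadata (µm by default). The format
is deliberately tool-agnostic: any tracking software that exports positions
and lineage links can feed it.

## Worked example

```python
from trackforest import (SimConfig, simulate_forest, build_forest, classify_trees,
                         population_growth_curve, fit_growth_polynomial, kinship)

cfg = SimConfig(duration_h=60.0, frame_interval_h=0.25, n_roots=60,
                division_mean_h=18.0, division_sd_h=2.0,
                death_hazard_apoptotic=0.01, death_hazard_necrotic=0.005,
                resistant_fraction=0.25, heritability=0.8, speed_mult_sd=0.3)
ds = simulate_forest(cfg, seed=1)

forest = build_forest(ds)
labels = [c.label for c in classify_trees(forest).values()]
print({lab: labels.count(lab) for lab in ("NO_DEATH", "SURVIVING", "EXTINCT")})

curve = population_growth_curve(forest, mode="FROM_START")
fit = fit_growth_polynomial(curve)
print(f"P3(t) = 100 + {fit.a:.3f} t + {fit.b:.4f} t^2 + {fit.c:.6f} t^3")

sisters = kinship.first_generation_sisters(forest)
daughters = [d for _, d1, d2, _ in sisters for d in (d1, d2)]
mem = kinship.estimate_memory_time(
    kinship.msd_curves(forest, daughters, t_max_h=15.0, step_h=0.5))
print(f"memory time {mem.persistence_h:.2f} h over {len(daughters)} daughters")

pairs = kinship.subtree_length_pairs(forest, horizon_h=40.0, birth_window_h=30.0)
print(f"{len(pairs)} sister pairs, r = {kinship.pair_correlation(pairs):.2f}")
```

prints

```
{'NO_DEATH': 23, 'SURVIVING': 20, 'EXTINCT': 17}
P3(t) = 100 + -1.094 t + 0.0803 t^2 + 0.000537 t^3
memory time 4.31 h over 92 daughters
46 sister pairs, r = 0.42
```

Reading the numbers: 23 of the 60 trees saw no death at all (the simulated
resistant fraction plus lucky vulnerable lineages), 17 died out. The negative
linear and positive quadratic growth coefficients capture early attrition
followed by proliferation. The fitted memory time (here upward of the
simulator's 3 h per-cell persistence because the small, trait-heterogeneous
cohort is noisy) measures how long daughters keep their direction of motion,
and the positive sister correlation of subtree track lengths reflects the
simulated heritability of the motility trait.

The same analyses are available from the shell — each run writes result CSVs
plus a `manifest.json` with parameters, input hashes and the package version:

```sh
trackforest simulate --out demo --seed 1
trackforest validate --tracks demo/tracks.csv --cells demo/cells.csv --out demo/check
trackforest report   --tracks demo/tracks.csv --cells demo/cells.csv --out demo/report
```

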