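# Methods

This note documents the statistical models and estimators implemented in
`trackforest`, the defaults and why they were chosen, what the synthetic
recordings do and do not emulate, and the numerical choices a maintainer
would want to know about.

## Data model

A recording is a pair of tables. The track table holds one row per cell per
observed frame (id, frame index, time in hours, x, y); the cell table holds
one row per cell (id, parent id or none, birth and end time, fate). Fates
are `DIVIDED` (always binary; the two daughters are born at the mother's end
time), `DEATH_APOPTOTIC` / `DEATH_NECROTIC` (the two morphologically
distinguished death modes), `ALIVE_AT_END`, and `LOST` (tracking failure /
left the field). `LOST` is admitted because it is unavoidable in real
tracking output; lost cells are counted as alive until their end time, then
leave the census without being deaths, and never make a tree "surviving".

"Alive at time t" means `birth ≤ t < end`, except that a cell alive at the
end of recording is also counted at `t = end`. The half-open convention
prevents double counting at a division instant: the mother is out, her
daughters are in, which is also why division-aligned growth curves start at
exactly 200 %.

The spatial unit is metadata only (µm by default); every statistic is
unit-agnostic. The paperwork trail for a run (parameters, input hashes,
package version) is written by the CLI to `manifest.json`.

## Root-frame selection

Analyses focus on the trees rooted in a centered rectangular frame "just
large enough" to contain a target number of starting cells (default 100).
The frame is centered at the midpoint of the bounding box of all time-zero
positions, keeps the field's aspect ratio, and is scaled by the smallest
factor for which at least the target number of roots lie inside (closed
boundary). For each root the minimal admitting scale is
`max(|x−cx|/(W/2), |y−cy|/(H/2))`; the selected scale is the n-th smallest
of these, so the rule is exact, not iterative. Roots tied exactly on the
minimal boundary are all included — "just large enough" pins down the scale,
not the cardinality — so the selection can exceed the target on degenerate
(gridded) inputs; with continuous coordinates ties have probability zero.

## Growth curves and the cubic model

`FROM_START` curves count the cells alive at each grid time in the selected
trees, as a percentage of the time-zero count. `POST_FIRST_DIVISION` curves
align each tree at its own first division, express its census as a
percentage of the single founder, and average the per-tree percentage curves
without weights over the trees that have divided and are still within the
recording at each aligned time. The default grid step is the frame interval.

Curves are compressed to three numbers by `P3(t) = 100 + a·t + b·t² + c·t³`.
The intercept is not fitted: `y − 100` is regressed on the basis
{t, t², t³} by least squares, so `P3(0) = 100` holds exactly and the model
is a pure-compression device, not a mechanistic growth law. The cubic is
solved with `numpy.linalg.lstsq` (rank-checked); tests verify agreement with
the explicit normal-equations solution to 1e-8 relative.

The "largest trees" ranking used for sub-cohort curves orders trees by
member count alive at the end of recording (ties by root id); ranking by
total cells ever born is available as a documented alternative
(`largest_trees(by="total_ever")`).

## Trajectory smoothing, speed, track length

Raw tracked positions are noisy and frame-quantized, so speed is defined
through the Nadaraya–Watson Gaussian-kernel estimate

    x̂(t) = Σᵢ wᵢ(t)·xᵢ / Σᵢ wᵢ(t),   wᵢ(t) = exp(−(t−tᵢ)²/(2h²)),

with the bandwidth h interpreted as the Gaussian standard deviation,
default 0.25 h (15 min). The normalized (Nadaraya–Watson) form rather than
a plain convolution makes the estimate robust to irregular or missing
frames. Speed is the norm of the *analytic* derivative of the estimate —
finite differences of raw points would make speed depend on the recording
resolution. Track length over an interval is the trapezoid-rule integral of
speed on a grid no coarser than the frame spacing; it is additive over
adjacent intervals and invariant under rigid motions and time reversal
(tested to 1e-9).

Numerics: the kernel is truncated at ±6σ. The discarded mass (~1e-9) is
negligible, so truncation is purely an efficiency device; a tighter ±4σ cut
was rejected because the asymmetric edge clip introduces ~1e-4 relative
errors in interpolated positions. If an evaluation time has no sample
within the truncated support (a gap larger than 6σ, impossible on a regular
grid at the default bandwidth), the position falls back to the nearest
sample and the velocity to zero.

Windowed speed is summarized by the generalized power mean
`M_p = (mean vᵖ)^(1/p)` over a centered window (default 8 h), computed only
at centers whose full window fits inside the lifespan. `M₁ ≤ M₂ ≤ M₄` holds
exactly (power-mean inequality); larger p upweights the fastest episodes,
which makes `M₄` more sensitive to transient motility bursts than the plain
mean. Distribution summaries pool per-cell `M_p` values into fixed time
bins with fixed, configurable histogram edges so runs remain comparable.

## Sister-pair statistics

The two daughters of a root's first division share birth place and
inheritance, so joint statistics of their subtrees probe heritability.
Pairs are unordered; every analysis symmetrizes them (each pair enters as
(v₁,v₂) and (v₂,v₁)), which forces the two marginals to share mean and
variance and makes every statistic invariant to within-pair order.

* **Descendant counts** (default horizon 70 h after the sisters' birth,
  sisters born within 20 h of the recording start): for each daughter, the
  number of distinct descendant cells *born* within the horizon — the
  cumulative reading; counting only cells still alive at the horizon is a
  documented switch (`count_mode="alive_at_horizon"`).
* **Smoothed count histogram**: counts on the integer lattice convolved
  with an isotropic Gaussian of σ = 1.5 lattice (count) units — the only
  plausible scale for count data — truncated at 4σ and renormalized so the
  total mass equals twice the number of pairs exactly.
* **Subtree track lengths** (default horizon 60 h, sisters born within
  30 h): per daughter, the sum over her subtree of each member's track
  length truncated to [member's birth, sisters' birth + horizon]. The
  truncating reading was chosen over including whole lifespans of cells
  born before the horizon so that both sisters are measured over identical
  time windows. Cells observed in fewer than two frames have no measurable
  path and contribute zero.
* **Joint KDE**: Gaussian product KDE (scipy's `gaussian_kde`) on the
  symmetrized sample with Scott's rule — empirical covariance scaled by
  n^(−2/(d+4)), d = 2, with n the symmetrized sample size, since that is
  the sample the estimator is fed. The density is evaluated on a grid
  padded by a configurable number of marginal kernel widths; at the
  default padding the grid integral is within 2 % of 1.
* **Correlation**: Pearson correlation of the symmetrized values; positive
  values indicate inheritance from the common mother.

Mode counting on a joint density (`n_local_maxima`) labels connected
components of strict 8-neighbourhood maxima above a relative threshold
(default 20 % of the peak) so that shot noise in sparse histograms does not
register as clusters.

## Displacement curves and memory time

With r(t) the displacement of a cell t hours after its birth, the cohort
summaries are mean `c(t) = r(t)·r(t)`, mean `c(t)/t` (the mean is divided
by t, not averaged per-cell after division — identical for a fixed-t cohort,
and the per-point counts expose attrition), and the sibling
cross-displacement mean `c₁,₂(t)/t = r₁(t)·r₂(t)/t` over sister pairs with
both sisters alive at the lag. Cells (or pairs) that divide or die before a
lag simply drop out of the mean at that lag. Per pair and lag,
`|r₁·r₂| ≤ (|r₁|² + |r₂|²)/2` holds exactly and is asserted in tests.

Two estimator details matter:

* **Raw anchors.** Displacements are measured on the raw frame positions
  (linearly interpolated), not on kernel-smoothed ones. Smoothing the birth
  anchor averages a one-sided kernel window over the early path, which
  correlates the anchor with the path and subtracts an O(bandwidth)
  constant from c(t) — enough to destroy the flat-`c(t)/t` diagnostic for
  memoryless motion at the default bandwidth. Smoothed anchors remain
  available (`use_smoothed=True`) for data whose positional noise dominates.
* **Anchor time.** Births fall between frames; lags are measured from the
  first observation at or after the birth, so every lag is exact. Anchoring
  at the nominal birth while sampling the far point at `birth + t` would
  shorten lags by up to one frame and bias c(t) low at small t.

The directional **memory time** is the persistence time P of the Fürth
(persistent random walk) form `c(t) = 4D(t − P(1 − e^(−t/P)))`, fitted to
mean c(t) by bounded least squares (`scipy.optimize.least_squares`,
P ∈ [grid step, 10·t_max], D > 0). The fit minimizes *relative* residuals:
the sampling noise of a mean squared displacement scales with its value, so
relative residuals weight the grid approximately uniformly, while an
unweighted fit lets the noisy large-t points dominate and roughly doubles
the variance of P̂. Initialization takes 4D from the late plateau of c(t)/t
and P from the half-plateau crossing (≈ 1.6 P for the Fürth curve). A P̂ at
the lower bound flags effectively memoryless motion ("low" censoring); at
`P ≥ t_max` the window never left the ballistic regime ("high" censoring)
and only a lower bound on P is claimed.

Diagnostics for hypothesis-style checks: `flatness_slope` tests the slope
of mean c(t)/t with a *cell-level* standard error (per-cell slopes are
i.i.d. and their mean equals the slope of the mean curve on a common grid;
the naive regression SE is invalid because the grid values share the cells'
cumulative increments), and `cross_msd_zero_test` tests the mean of
per-pair time-averaged c₁,₂(t)/t against zero with the cross-pair SE.

## Proximity events

An event is a maximal interval during which an unordered pair of
concurrently-alive cells stays within a center-to-center distance threshold,
with interruptions up to `max_gap` (default one frame interval, so a single
missing or flickering frame does not split an event), intersected with
times at least 2 h after *both* cells' births (a "sisters-only" exclusion
mode is available), and at least 4 h long. The distance threshold is a
run-time configuration constant — the CLI default of 30 length units is a
typical adherent-cell diameter, a convenience rather than a claim. Distances
are evaluated on the raw frame grid; candidate pairs are prefiltered with a
k-d tree per frame, and the detector's contract (tested) is exact
equivalence to the brute-force all-pairs scan. Events attach to the trees of
their members; cross-tree events attach to both trees, so per-tree
cross-tree attachments sum to exactly twice the cross-tree event count.

## Synthetic recordings

The simulator emulates the recording geometry the analyses assume: root
cells uniform in a rectangular field at time zero (defaults 200 roots in a
1400 × 1050 µm field, 94 h at 6-min frames, so a 100-cell analysis frame is
selectable), binary divisions, two competing death hazards, observation on
the frame grid with additive Gaussian position noise (default σ = 0.5 µm).

**Motion.** Each velocity component is an Ornstein–Uhlenbeck process with
relaxation (persistence) time P (default 3 h) and stationary standard
deviation `speed_scale` (default 15 µm/h per component, mean speed
≈ 19 µm/h — a realistic epithelial-cell scale). Position and velocity are
advanced jointly with the *exact* discretization of the integrated OU
process at every step (the 2×2 noise covariance per step is Cholesky-
factored), so the Fürth MSD form holds exactly in expectation at all lags
— the family presupposed by the displacement diagnostics. D equals
`speed_scale² · P` (675 µm²/h at defaults). A `brownian` mode substitutes
pure diffusion at a stated D.

**Heritability.** Each lineage carries a division-time trait and a
log-speed multiplier. At division, `trait_child = w·trait_parent +
(1−w)·population draw` with heritability weight w (log-space for the speed
multiplier, so the stationary trait distribution is preserved); w = 0 gives
i.i.d. cells, w = 1 perfect inheritance. The division-time population can
be a mixture of types, and a configurable fraction of root lineages is
"resistant" (zero death hazard, inherited exactly). Death times are
exponential with mode-specific hazards; per-cell division times are normal
around the lineage trait (a deterministic division clock when the sd is 0).
An optional generation cap (`max_generations`) freezes division beyond a
given generation, which is how fixed first-generation cohorts are produced
for displacement studies. Death and loss waits are clamped to at least two
frames so every cell is observed at least once.

**Sisters.** Daughters start at the mother's last position with initial
velocities `c·shared + √(1−c²)·independent` (coupling c preserves the
stationary law while correlating headings), and can optionally feel a
transient mutual spring (Euler-coupled on top of the exact OU step) — the
mechanism behind positive sibling cross-displacement and prolonged
proximity.

**What is not emulated.** No cell morphology or imagery, no spatial
crowding or boundary effects (cells may drift out of the nominal field), no
corpse tracks after death, no microenvironment. Passing tests therefore
validate the statistical machinery under the stated generative model, not
the biology of any particular experiment.

Same config and seed reproduce a byte-identical dataset. `perturb_positions`
adds i.i.d. Gaussian noise to every coordinate (lineage untouched) for
sensitivity studies of the smoothing/threshold choices.

## Problem sizes in the test suite

The suite exercises the pipeline at sizes chosen to make every stochastic
check well-powered while keeping a full run around half a minute: 2,000
Brownian daughters for the flatness diagnostics, 500 persistent-walk
daughters for memory-time recovery (±25 % band; the estimator's sampling sd
at this size is ≈ 0.25 h around the true 3 h), 100 forests for the
classification partition, 100-root forests for the heritability signatures,
and 50 seeds for the proximity invariants.

## Known limitations

* The growth cubic is descriptive; extrapolating it beyond the fitted
  window is meaningless.
* The memory-time estimator assumes a single persistence scale; cohorts
  mixing heterogeneous persistence (or strongly attrited cohorts) return an
  effective P between the component scales, and small cohorts carry
  substantial sampling error (the worked example in the README shows 4.3 h
  for a 92-cell heterogeneous cohort simulated at 3 h).
* Descendant-count and subtree-length horizons silently truncate at the end
  of recording; horizons extending beyond `duration − birth_window` are
  right-censored for late-born sisters.
* Proximity uses center-to-center distance — cell size and shape are not in
  the data model — and the threshold is a user choice.
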