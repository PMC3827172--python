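# Methods

This note records the modelling assumptions, the numerical and design
choices that were genuinely open, and what the synthetic studies do and do
not demonstrate.

## Dynamics

The state is a boolean species × cell matrix on a rectangular lattice.
Updates are synchronous with a one-year time step: all update probabilities
are computed from the state at `t` before any draw, then presence at `t+1`
is an independent Bernoulli trial per (species, cell), and finally the
richness cap prunes over-full cells. Asynchronous sweeps were rejected
because they make results depend on cell visiting order.

* **Persistence branch.** A species present in a viable cell stays with
  probability `P_E(e)`; extinction is its complement. `P_E` depends only on
  the cell's environment (constant, single-covariate threshold, or logistic
  on named covariates). A consequence the tests assert: without immigration
  and with `P_E < 1`, occupancy decays geometrically and every replicate
  eventually goes extinct — there is no local rescue.
* **Colonisation branch.** A vacant viable cell is colonised with
  `P_I · P_E`, immigration and subsequent persistence being treated as
  independent. `P_I` is the union of independent per-source arrivals from
  every occupied cell within the species' cutoff.
* **Distance.** Chessboard (Chebyshev) distance in cells: the first ring
  around an interior cell has 8 cells and the ring at distance `d` completes
  a `(2d+1)² − 1` neighbourhood. Grid edges are absorbing voids (no wrap;
  off-grid cells send nothing). Non-viable cells (sea, destroyed habitat)
  can never be occupied but are crossed by dispersal: the kernel is a pure
  function of distance. Whether real dispersers would cross such terrain is
  a biological question the model deliberately does not resolve.
* **Kernel.** `p(d) = p_max (d_max − d + 1)/d_max` on support `1..d_max`.
  The linear-decline family admits two natural discretisations — reaching 0
  at `d_max` or at `d_max + 1`. We use the latter: it keeps the kernel
  defined and non-degenerate at `d_max = 1` (a species whose dispersal is
  confined to the adjacent ring, which realistic parameterisations need)
  and equals `p_max/d_max` at the cutoff. The choice is isolated in
  `dispersal_prob` for easy substitution. Long-distance (fat-tailed)
  dispersal is out of scope.
* **Richness cap.** Enforced after the draws, on the union of survivors and
  successful colonisers: candidates are sorted by persistence probability
  *in the focal cell* (species sorting — the locally best competitors win)
  and the top `S_max` remain. Ties are broken by a seeded uniform draw so
  equally competitive species are exchangeable rather than favoured by
  index order. Initial states (e.g. full occupancy for burn-in) may exceed
  the cap; every state produced by an update respects it, which the tests
  assert along whole trajectories.
* **Trade-off.** `d_max = round(d_min / C_j)` (half-up, floored at 1 cell),
  with competitive ability `C_j` the species' maximal persistence over the
  viable study area. `C_j` is computed once at configuration time and is
  deliberately not recomputed when cells are later destroyed mid-experiment.

## Random numbers and reproducibility

One master integer seed per run. Replicates use substreams spawned from the
master `SeedSequence`, so replicate `r` is reproducible in isolation and
replicate fields are bit-for-bit stable across reruns. Within a step, a
single generator serves the Bernoulli draws and the cap tie-breaks.

## Estimation

The fitting criterion is the Bernoulli negative log pseudolikelihood between
an observed presence/absence snapshot and the simulated occurrence
probability, with `q` clipped to `[ε, 1−ε]`, `ε = 10⁻⁶` by default. We also
report `G = exp(−NLL/N)`, the per-observation geometric-mean likelihood: a
[0, 1] score comparable across data sizes and our operationalisation of a
"pseudomaximum likelihood" goodness value. Search is an exhaustive grid —
the cutoff is integral by definition, the simulated criterion is noisy, and
small exact grids are reproducible where continuous optimisers are not.
Candidates share replicate seeds (common random numbers) to reduce
comparison noise. Two community-level hypotheses are fitted head-to-head:
one shared `d_max` (neutral dispersal) versus one shared `d_min` with
per-species `d_max` from the trade-off (patch dynamics).

**Identifiability.** On a homogeneous landscape at `p_max = 1`, the
marginal occurrence field is nearly invariant to `d_max` once the
population is viable, so a single snapshot cannot pin the cutoff down; the
criterion surface is flat to a few nats across `d_max ≥ 2`. The packaged
recovery study therefore uses a suitability gradient (a benign source strip
at threshold persistence 0.95 beside hostile habitat at 0.10): occupancy
bleeds past the edge over a cutoff-dependent length scale, which the fit
reads. Even in this design the estimate from one 20×20 binary snapshot has
a sampling spread of about one cell: across repeated synthetic truths the
estimator is centred on the truth and lands within ±1 cell in roughly nine
seeds of ten, but exact hits occur in only about half — and quintupling the
Monte-Carlo replicates does not improve this, showing the binding noise is
the observation itself, not the simulated `q`. Point estimates of `d_max`
from single snapshots should accordingly be read as ±1 cell.

## Simulation studies

All studies run 50 years from full occupancy of viable cells and average
over replicates; horizons and replicate counts are configurable (defaults
30 replicates for the virtual-community studies, 100 for the valley
destruction study; the suite's smoke tests use smaller values). The
"stable distribution" horizon is fixed, not auto-detected.

* **Virtual community.** 30 species on one habitat: constant persistence ~
  U(0.7, 0.9), cap 20 species/cell, shared `p_max`, integer `d_max` ~
  U{1..6}. Two parameterisations: *local* (1 km cells, `p_max = 1`) and
  *regional* (20 km cells, `p_max = 0.02` — when a cell is far larger than a
  home range, only a small fraction of its occupants reach the next cell).
* **Mainland–island.** An explicit mainland block (40×20 cells), a
  non-viable sea strip and an island block evolve together; distance is the
  chessboard distance between closest shores. At regional parameters,
  island richness declines steeply with isolation and area; at local
  parameters only very small islands are impoverished. A mainland-only
  control reduces to the homogeneous simulator.
* **Mid-domain.** A homogeneous bounded 40×40 domain. The contrast is the
  central 10×10 block's mean richness minus the edge ring's (width 5),
  tested one-sided over replicates. Boundaries intercept immigration, so a
  richness bulge appears at regional parameters and vanishes at local ones
  where immigration is saturating.
* **Matrix destruction.** The viable non-forest matrix becomes non-viable
  (100% mortality); both scenarios start from full occupancy of their
  viable area with identical replicate seeds. Reported from the occurrence
  fields over forest cells: total richness (species with nonzero mean
  forest occurrence), mean per-cell richness, and per-species forest
  occurrence before/after. Destroying an all-forest landscape is a no-op.

## The synthetic valley fixture

`generate_vanera_like_fixture` emulates the structure of a point-count
survey of a mountain valley: a 19×24 grid whose 214 surveyed cells hug a
sinuous valley axis, altitude 1.1–2.6 km rising toward the flanks, five
clustered habitat classes (lowland, heath, grassland, dense and clear pine
forest) with richness caps 17/16/11/14/14 and pine on 30% of the surveyed
area, semi-quantitative cover covariates (0–9) plus altitude and a pine
indicator, and a 45-species community in three guilds (24 open-lowland, 14
pine-forest, 7 high-altitude) with jittered logistic persistence models,
`p_max = 1` and a 7-cell dispersal cutoff. Pseudo-observations are one
realised state after 50 years of burn-in. Everything is generated by code
from a seed; no survey data ship with the package. The fixture reproduces
the qualitative phenomena (guild-structured co-occurrence networks,
source–sink matrix birds in the forest, the total-vs-per-cell richness
contrast under matrix destruction) but its absolute richness levels depend
on the invented coefficients, so numbers computed on it characterise the
fixture, not any real valley; likewise, passing tests on it demonstrate
model behaviour, not predictive skill on field data.

## Numerical notes

* Immigration unions are computed in log space (`log1p`/`expm1`) via a
  per-species convolution of the occupancy indicator with a
  `log(1 − p(d))` kernel (species sharing a kernel are batched); kernel
  probabilities are clipped to `1 − 10⁻¹⁵` so `p = 1` stays finite, and an
  exact-1 source short-circuits the scalar union.
* The cap sort runs only on cells whose candidate count exceeds their cap,
  via a single `lexsort` over (persistence, uniform tie-break).
* Pearson correlations of zero-variance occurrence vectors are undefined;
  such species are flagged NaN and skipped when thresholding edges
  (|r| > 0.5 by default) rather than emitting NaN edges.
* Degenerate inputs fail loudly: no viable cells, empty candidate grids,
  empty forest masks, probabilities outside [0, 1], perfect separation in
  the logistic fit (warn + clip at |log-odds| = 30).

## Known limitations

Presence/absence only — no abundance, demography or age structure; linear
kernel precludes long-distance colonisation events; persistence is
conflated with fitted occurrence probability (no detection model); the cap
is a hard competitive ceiling rather than pairwise interactions; `C_j` is a
scalar summary of the whole niche. These mirror the model's design goals of
minimalism and data frugality rather than accidental omissions.
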