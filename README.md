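# ndm — a stochastic niche-and-dispersal model of species distributions

`ndm` simulates the presence/absence of a community of species on an
explicit grid, treating local occupancy as a yearly balance between
niche-based persistence and distance-limited immigration. It is aimed at
spatial ecologists and metacommunity modellers who want a minimal,
presence/absence-only engine that nevertheless reproduces classic community
patterns — island species–area/isolation relationships, the mid-domain
effect, and the response of a focal habitat's community to destruction of
the surrounding matrix — and supports fitting its dispersal parameters to
observed occurrence snapshots.

## The model

Each cell `e` of a rectangular lattice carries a habitat class, covariates
and a viability flag. Each species `j` has

* a persistence probability `P_E(e)` — the probability that an individual
  present in `e` is still there next year, a function of the cell's
  environment only (constant, threshold, or logistic on covariates);
* a dispersal kernel on chessboard distance `d` (cells):
  `p(d) = p_max (d_max − d + 1)/d_max` for `1 ≤ d ≤ d_max`, else 0.

With `K` the occupied cells within `d_max` of `e`, immigration is the union
of independent arrivals, `P_I = 1 − Π_{k∈K} (1 − p(d_{k,e}))`, and a vacant
cell is colonised with probability `P_C = P_I · P_E`. Presence at `t+1` is
a synchronous Bernoulli draw per (species, cell): success probability `P_E`
if present, `P_C` if absent. Interspecific competition enters through a
habitat-specific richness cap `S_max`: when more species land in a cell
than its cap allows, they are ranked by persistence probability in that
cell and only the top `S_max` remain (ties broken at random). A
competition–dispersal trade-off is available as `d_max = round(d_min/C_j)`,
where the competitive ability `C_j` is the species' maximal persistence over
the study area.

Occurrence probabilities `q_e` are Monte-Carlo means of final presence over
replicate runs. Dispersal parameters (`p_max`, `d_max` or `d_min`) are
estimated by exhaustive grid search minimising the Bernoulli negative log
pseudolikelihood `−Σ [y ln q̃ + (1−y) ln(1−q̃)]` between an observed
snapshot `y` and the simulated `q̃ = clip(q, ε, 1−ε)`; the per-observation
geometric-mean likelihood `G = exp(−NLL/N)` is reported alongside.

## Worked example

Generate the synthetic mountain-valley fixture (a 19×24 grid with 214
surveyed cells, five capped habitats, ~30% pine forest and a 45-species
community in three habitat guilds), then ask what happens to the forest
birds when the surrounding non-forest matrix is destroyed:

```python
import numpy as np
from ndm.experiments import generate_vanera_like_fixture, run_matrix_destruction
from ndm.simulator import SimulationConfig

L, species, obs = generate_vanera_like_fixture(seed=1)
forest = np.isin(L.habitat, ["dense_pine", "clear_pine"]) & L.viable
report = run_matrix_destruction(
    L, species, forest, SimulationConfig(years=50, replicates=100, seed=2)
)
print(report.summary)
```

```
{'forest_total_richness_before': 39, 'forest_total_richness_after': 22,
 'forest_mean_cell_richness_before': 13.8925, 'forest_mean_cell_richness_after': 13.4371875}
```

Total forest richness collapses (39 → 22 species) while the *per-cell*
mean barely moves (13.9 → 13.4): the species lost are matrix birds that
persisted sparsely in the forest only through mass immigration from outside
— a source–sink signature the per-cell average is blind to. The same
pipeline is available from the shell:

```sh
ndm fixture --seed 1 --out fx/
ndm simulate --landscape fx/landscape.csv --caps fx/caps.yaml \
    --species fx/species.csv --coeffs fx/coeffs.csv \
    --years 50 --reps 100 --seed 2 --out sim/
ndm network --field sim/occurrence.csv --landscape fx/landscape.csv \
    --caps fx/caps.yaml --out net/
```

`ndm experiment island|middomain|matrix` runs the packaged simulation
studies; every command writes a `provenance.json` recording inputs,
parameters and seed.

## Layout

| module | contents |
| --- | --- |
| `ndm.landscape` | grid, habitats, covariates, viability, richness caps, Chebyshev geometry |
| `ndm.persistence` | persistence models, competitive ability, logistic fitting |
| `ndm.dispersal` | kernel, immigration union, colonisation, trade-off |
| `ndm.simulator` | synchronous stochastic dynamics, richness-cap sorting, replicate fields |
| `ndm.estimation` | pseudolikelihood criterion and grid-search fits |
| `ndm.experiments` | virtual communities, valley fixture, island / mid-domain / matrix studies |
| `ndm.network` | co-occurrence correlation networks, Pajek / edge-list export |
| `ndm.io`, `ndm.cli` | CSV/YAML/ASCII-grid readers and writers, `ndm` command |

See `docs/methods.md` for modelling assumptions, parameter choices and
known limitations.
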