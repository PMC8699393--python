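# lineagepump

Lineage-aware quantification of intercellular fluorescence transfer in
co-culture time-lapse experiments.

## The problem

When fibroblast-like donor cells (HDF) are co-cultured with
osteosarcoma-like acceptor cells (SAOS-2), donor membrane label (DiD)
moves into acceptors by cell-projection pumping and related contact
mechanisms. Single-cell tracking of such co-cultures yields, per cell, a
lineage position (mother/daughter/sister links, generation, fate), shape
measures, centroid trajectories and a summed fluorescence signal. The
scientific question is twofold: **does the amount of label a cell receives
correlate with its phenotype** (cell-profile area, circularity, migration
velocity, propensity to divide), and **does that phenotypic effect survive
mitosis** into the daughters?

`lineagepump` implements the complete analysis:

* **Fluorescence accounting.** Values are normalized so the median
  fluorescence of starting-generation co-cultured acceptors is 100 units.
  Each cell gets `Fa` (its normalized fluorescence at the final
  fluorescence frame) and the mother-compensated
  `Fmc = Fa + Fa(mother)/2`, which restores the half of the mother's
  label handed to the sister at division; `Fmc = Fa` for the starting
  generation. Rates `Fa/day`, `Fmc/day` divide by each cell's observation
  span.
* **Morphometrics.** Circularity `4πA/P²` from measured area and
  perimeter, or from segmentation masks (marching-squares contour with
  staircase relaxation); masked fluorescence summation over intensity
  rasters.
* **Migration velocity.** Path length over tracked time on a ≥2 h centroid
  grid with the last-interval rule (a final interval shorter than the grid
  spacing removes the preceding grid point).
* **Association statistics.** Kendall's tau-b (tie-adjusted,
  continuity-corrected p) of each phenotype against `Fa` and `Fmc`, per
  generation and for cumulative generation groups; sister-pair difference
  correlations; dividing-vs-non-dividing uptake-rate comparison with the
  proportionate ratios `pFa`, `pFmc` (Mann–Whitney U); one-sample and
  paired Wilcoxon cross-experiment tests.
* **Persistence index.** Per experiment, score +1 / 0 / −1 by whether the
  `Fmc` correlation beats the `Fa` correlation (sign-flipping a pair when
  the `Fa` tau is negative); average across experiments and map to
  `(1 + score)/2 ∈ [0, 1]`. For mitosis the same scoring compares `pFmc`
  with `pFa` (ties score −1).
* **Synthetic co-cultures.** An agent-based simulator with asynchronous
  log-normal division times, gamma-process label uptake, exact halving at
  division, monotone phenotype couplings and per-phenotype persistence
  switches (`reset` / `inherit`), writing the same track-table schema the
  readers consume.

## Worked example

```python
from lineagepump import LineageTransferModel, simulate_batch

forests = simulate_batch(seed=1)          # 7 experiments, study durations
results = LineageTransferModel(forests).fit()
print(results.summary())
```

prints (seed 1):

```
Lineage fluorescence-transfer analysis
============================================
experiments: a, b, c, d, e, f, g

area (grouping: all)
  median tau Fa +0.55 (p vs 0: 0.0156), Fmc +0.41 (p vs 0: 0.0156)
  persistence index 0.00 (scores [-1, -1, -1, -1, -1, -1, -1])
circularity (grouping: generations-0+1)
  median tau Fa -0.35 (p vs 0: 0.0156), Fmc -0.51 (p vs 0: 0.0156)
  persistence index 1.00 (scores [1, 1, 1, 1, 1, 1, 1])
velocity (grouping: all)
  median tau Fa +0.19 (p vs 0: 0.0156), Fmc +0.13 (p vs 0: 0.0156)
  persistence index 0.00 (scores [-1, -1, -1, -1, -1, -1, -1])
mitosis (pFa vs pFmc)
  persistence index 0.00 (scores [-1, -1, -1, -1, -1, -1, -1])
```

Read: area correlates strongly with received label (median tau ≈ 0.5) but
the simulated area driver *resets* in daughters, so compensating the
mother's share (`Fmc`) only weakens the correlation — every experiment
scores −1 and the persistence index is 0. The circularity driver is
*inherited*, so `Fmc` beats `Fa` everywhere and the index is 1. These are
exactly the ground-truth switches of the default
`SimulationConfig` (`persistence_area="reset"`,
`persistence_circularity="inherit"`, `persistence_velocity="reset"`).

The same pipeline runs from the shell:

```bash
lineagepump simulate --seed 1 --out-dir sim
lineagepump run sim/tracks.csv --out-dir results
lineagepump reproduce-tables
```

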