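# scalepart

Multi-scale variance partitioning of species composition against groups of
environmental variables.

## The problem

How much of the spatial turnover in community composition is attributable to
climate, to topography, to land use/land cover (LULC), and to primary
productivity (NDVI) — and how does the answer change with the spatial scale
of observation?  Two distinct elements set a variable group's apparent
importance: the strength of species' ecological *affinity* to it, and the
amount of *variability* the group exhibits within the sampled window.  A
group can matter because organisms respond strongly per unit change (high
affinity, e.g. climate, which varies smoothly and little), or because it
simply varies a lot (e.g. patchy LULC mosaics).  `scalepart` implements the
full analysis chain needed to measure and disentangle the two, driven by a
virtual-ecologist generator so every stage is testable without downloads.

## The method

Occurrence records (Darwin-Core-style CSV) are quality-filtered — only
records whose longitude *and* latitude are written with ≥ 3 decimal digits
survive, plus an optional species whitelist — and aggregated into square
**sampling grids** of 32 × 32 cells.  Spatial scale is the pair (grain *g*,
extent *E*): *g* is the cell area, *E* = 1024 · *g* the grid area, and *g*
doubles between consecutive scales (10, 20, 40, … km² in the reference
design, spanning 10–10 240 km² grains over 11 scales).  A grid enters the
analysis when it has ≥ 30 cells holding more than one record and ≥ 6
species.

Environmental layers are resampled to each grain (cell mean for continuous
variables, modal class for categorical; the categorical LULC layer also
yields per-class percent-cover layers, and elevation range is the cell
max − min).  For each qualifying grid, the cells × species count matrix *Y*
is related to the cells × variables matrix *X* by **canonical correspondence
analysis** built from scratch: with *P = Y/N*, row/column masses *r, c* and

&nbsp;&nbsp;&nbsp;&nbsp;*Q*ᵢⱼ = (*p*ᵢⱼ − *r*ᵢ*c*ⱼ) / √(*r*ᵢ*c*ⱼ),

total inertia ‖*Q*‖² equals the Pearson χ²/N of the table.  CCA projects
*Q* on the weighted, centered constraint space; **partial CCA** first
residualizes on a conditioning set, so the constrained inertia of
pCCA(*Y*, *X*₉ | *X*₋₉) is the variance attributable *exclusively* to group
*g*.  Each grid's inertia is partitioned into exclusive percents per group
(× 100 / total inertia), the joint percent of all groups, and their overlap.

Per-scale means of exclusive explained variance are then regressed (OLS,
df = (1, *n*−2)) on per-scale means of the group's **coefficient of
variation** (sd/mean of the 1024 cell values; the variance/mean convention
is available as an option).  A positive relationship says the group's
impact tracks its variability; high explained variance at low CV indicates
strong affinity.

## Worked example

```python
from scalepart import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="demo_out",
    synthetic=dict(width_px=128, height_px=128, patch_scale=6.0),
    n_species=12, n_target=30000, n_scales=2, base_grain=4.0,
    group_affinity={"climate": 1.0, "lulc": 1.0}, seed=42,
)
run_pipeline(cfg)
```

or equivalently `scalepart run-all --config demo.yaml`.  The run writes
`grids.csv`, `partitions.csv`, `cv.csv`, `group_cv.csv`,
`scale_summary.csv`, `regressions.csv`, a log and the resolved config.
`scale_summary.csv` for this configuration reads:

```
 scale  n_grids  joint_pct  climate_pct  lulc_pct  topography_pct  ndvi_pct  climate_cv  lulc_cv
     1        3     52.282        6.989    20.232           0.482     0.314       0.164    2.023
     2        1     43.821       11.094    12.285           1.313     0.699       0.186    1.851
```

Read: at the 4 km² grain, the four groups jointly explain 52.3% of the
compositional inertia in the average qualifying grid; LULC's exclusive
share (20.2%) dominates climate's (7.0%), and the within-grid variability
of LULC (CV ≈ 2.0) is an order of magnitude above climate's (CV ≈ 0.16) —
the community responds to both, but LULC also *varies* far more.  At the
coarser grain the two groups converge (12.3% vs 11.1%).

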