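# phytoreg

Quantitative biogeographic regionalization from species occurrence records.

Given point records of many species (herbarium-style tables: species name,
longitude, latitude) and per-cell environmental variables, `phytoreg`
delimits **phytogeographic districts** — subdivisions of a biogeographic
province characterized by their own species assemblages — and identifies
the environmental gradients behind them. It is aimed at biogeographers and
conservation planners who want a reproducible, scriptable version of the
classic turnover-based regionalization workflow.

The pipeline:

1. **Gridding** — curate records (coordinate checks, optional study-region
   polygon), bin them into 0.25° cells, exclude cells with < 5 records and
   fold their records into neighbouring cells.
2. **Turnover** — pairwise beta-Simpson dissimilarity between cells,
   `βSim = 1 − a/(a + min(b, c))`, which ignores richness imbalance and
   measures true species replacement.
3. **Districts** — WPGMA (McQuitty) clustering of the turnover matrix, cut
   into k groups, minor groups consolidated into the main districts;
   significance by MRPP (multi-response permutation procedure).
4. **Ordination** — non-metric multidimensional scaling (Kruskal stress-1)
   with per-axis, sign-fixed scores for mapping.
5. **Environment** — collinearity pruning, z-standardization, redundancy
   analysis (RDA) with AIC-ranked, permutation-tested forward selection of
   predictors.
6. **Relative environmental turnover & tracks** — envfit-style vector
   fitting of the selected predictors onto the NMDS axes, district-
   exclusive species lists, and minimum-spanning-tree biogeographic tracks
   over their collecting points.

A synthetic-landscape generator (`phytoreg.synthetic`) plants the structure
the analysis assumes — two contiguous districts split at a 750 m elevation
threshold, district-exclusive plus shared species pools, heterogeneous
collecting effort, environmental layers with district-specific means (soil
Ca/Mg, precipitation variables) — so the entire pipeline is testable
end-to-end with no external data.

## Worked example

The numbered scripts in `analysis/` run the whole study on the default
synthetic landscape and write their tables under `results/synthetic_run/`:

```sh
cd analysis
python 01_simulate.py
python 02_grid.py
python 03_turnover.py
python 04_cluster_mrpp.py
python 05_ordination.py
python 06_environment_rda.py
python 07_ret_tracks.py
```

Selected output (seed 1):

```
simulated 2894 occurrence records of 99 species
landscape: 144 cells, 66 upper (A) / 78 lower (B)
...
betaSim over 144 cells x 99 species
mean 0.661, median 0.692, share of pairs > 0.8 (near-complete turnover): 23.0%
...
8 groups of sizes [78, 37, 9, 3, 9, 2, 4, 2]; consolidated into 2 districts (29 cells reassigned)
MRPP: delta=0.5425, expected=0.6607, A=0.1789, p=0.001
adjusted Rand index against planted districts: 1.000
...
NMDS (k=2, 21 starts): stress=0.2252 (fair), converged=True
NMDS1: district mean scores A=+0.355, B=-0.419
...
forward selection (Df, AIC, F, p):
variable  df        aic        f     p  cum_proportion
   MEXCA   1 658.389567 6.354732 0.001        0.042835
  BIO_17   1 655.059086 5.317237 0.001        0.077619
...
district A: 12 exclusive species
district B: 49 exclusive species
track A: 588 points, 587 edges, 3863 km total
```

Reading this: the eight WPGMA groups collapse into two districts that
reproduce the planted upper/lower split exactly (adjusted Rand index 1.0);
their floristic compositions differ significantly (MRPP p = 0.001, A > 0,
meaning within-district dissimilarity is ~18% below chance); the first NMDS
axis separates the districts; forward selection picks the planted soil-
calcium and driest-quarter-precipitation gradients — none of the decoy
variables — and both fit the ordination significantly (envfit p = 0.001).
The exclusive-species asymmetry (49 vs 12) mirrors the planted 50/10 pools.

The same machinery runs programmatically:

```python
from phytoreg import pipeline
cfg = pipeline.default_config(outdir="results/run", seed=1)
pipeline.simulate(cfg)              # writes occurrences/env/truth/cells
results = pipeline.run_pipeline(cfg)  # all stages + manifest.json
print(results["mrpp"].p_value, results["ordination"].stress)
```

For real data, point `cfg.paths.occurrences` / `cfg.paths.env` /
`cfg.paths.region` at your own CSV and GeoJSON files (configs can also be
loaded from YAML via `PipelineConfig.from_yaml`).

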