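# divscape

Toolkit for asking whether environmental conditions predict the genetic
diversity of plant populations scored with dominant markers (AFLP-style
presence/absence bands). It implements the full analysis chain as a tested,
reusable pipeline:

1. **marker_data** — read/validate/filter presence/absence matrices
   (individuals × band loci, one matrix per species; populations with < 5
   individuals dropped, datasets with < 5 surviving populations rejected).
2. **diversity** — per-population gene diversity
   `H_S = mean_j n_j/(n_j−1) · 2 p_j (1−p_j)` (small-sample-corrected
   pairwise-difference form) and genetic rarity (mean inverse number of
   populations carrying each band the target population carries).
3. **env_grid** — ESRI ASCII / GeoTIFF raster layers, cropping and
   containing-cell extraction at population GPS coordinates; 48 canonical
   environmental predictors (bio1–bio19 climate, 13 soil, 16 topography
   including the profile/tangential curvatures `pcurv`/`tcurv`). A
   pre-extracted table can be supplied instead of rasters.
4. **assoc** — pairwise Pearson correlation screen, Gaussian LASSO with a
   100-value log-spaced λ grid and cross-validation (fold count capped at n,
   i.e. leave-one-out for large requested fold counts), plus univariate OLS
   follow-ups pooled and per species (> 20 populations).
5. **spatial** — k-nearest-neighbour (k = 4, haversine) spatial weights and
   global Moran's I with permutation p-values.
6. **synth** — Balding–Nichols population-structure simulator with dominance
   masking, Gaussian-random-field environmental surfaces, and exact
   calibration for injecting a linear diversity–environment effect, so every
   stage has ground truth.
7. **pipeline / cli** — orchestration plus a `divscape` command-line tool.

## CLI

```bash
# synthesize a study bundle with a known pcurv effect
divscape simulate --seed 7 --n-species 3 --effect-beta 20 --out bundle/

# full analysis: filter -> diversity -> correlations -> LASSO (CV) ->
# pooled + per-species OLS -> per-species Moran's I
divscape run-all --markers bundle/markers_species_1.csv \
                 --markers bundle/markers_species_2.csv \
                 --markers bundle/markers_species_3.csv \
                 --env-table bundle/env_table.csv --out report/ --seed 1

# individual stages
divscape stats --markers bundle/markers_species_1.csv --out div.csv
divscape extract --grids elev.asc --points sites.csv --out env.csv
divscape associate --table report/diversity_env.csv --response Hs --out lasso.json
divscape spatial --table report/diversity_env.csv --variables Hs,pcurv --out moran.csv
```

`run-all` also accepts `--config config.yaml` (keys mirror
`divscape.pipeline.RunConfig`); explicit flags override the file. Every run
writes a `manifest.json` capturing inputs, settings, seed and versions, and
reruns with the same manifest are byte-identical.

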