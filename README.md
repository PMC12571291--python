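# evacflow

Analysis of post-disaster population mobility from **grid-aggregated mobile
location data**: hourly device counts per 1 km × 1 km cell, with no
individual trajectories. Such privacy-preserving panels are often the only
mobility data available after an earthquake, yet they still encode where
people gathered, which zones they abandoned, and along which corridors they
moved. `evacflow` is aimed at disaster-response researchers and analysts who
have (or want to prototype against) two matched weekdays of such counts — a
pre-disaster baseline day and a post-disaster day.

## What it computes

**Population anomaly.** For grid cell *i* and hour *t*,

```
D_it = P_post,it − P_pre,it
```

the post-disaster count minus the same-hour baseline count, removing the
diurnal cycle. Before differencing, cells with any run of ≥ 3 consecutive
missing hours on either day are dropped (behaviour can shift drastically
within three hours of a disaster, so longer gaps are unrecoverable), and
remaining isolated gaps are filled by linear interpolation.

**EOF decomposition.** The G×T anomaly matrix is row-centred to O′ and the
spatial covariance `C = O′O′ᵀ/(T−1)` eigendecomposed. Eigenvectors are the
spatial modes (EOFs), `PCs = O′ᵀ·EOFs` the temporal principal components,
and each eigenvalue's share of the trace the variance explained. A cell's
flow class follows from the sign product: positive loading × positive PC ⇒
population increase; negative loading × positive PC ⇒ decrease; reversed
when the PC is negative.

**BBAC_I co-clustering.** For comparison, rows and columns of the min-max
scaled raw count matrix are co-clustered by minimising the I-divergence
`F = D_I(O ‖ Ô)` between the matrix and its block-mean approximation Ô
(all hours in a single temporal cluster by default, so the clustering is
spatial but informed by the full time course).

**Route inference.** The negative-loading cores of an oriented mode are
evacuation origins, the positive cores destinations; minimum-cost paths
over grid adjacency with per-cell cost `1 − |loading|/max|loading|`
preferentially follow strong-loading corridors and operationalize the
qualitative "origins → corridors → destinations" reading.

Because operator panels of this kind are proprietary, the package ships a
synthetic scenario generator that plants sources, shelters, a transit
corridor, Poisson count noise and damage-correlated outage runs — every
stage is testable against known ground truth.

## Worked example

```sh
evacflow simulate --seed 2 --out sim/
evacflow run --panel sim/panel.csv --out out/ --seed 2
```

prints

```
wrote 300 grids to sim/panel.csv
valid grids: 215/300 (71.7%); EOF explained variance: 54.8%, 8.8%; BBAC_I loss 255.697; 432 routes
```

Of the 300 simulated cells, 215 survive the missing-run filter (outages are
deliberately more frequent in the hardest-hit zones, so the excluded cells
are concentrated there). The leading EOF mode (54.8% of variance) is the
evacuation ramp — source cells and shelter cells load with opposite signs —
and the second mode (8.8%) isolates the transient corridor bump. The
BBAC_I loss is the final I-divergence of the best-of-10-restarts
co-clustering; the route count covers every connected (origin, destination)
core pair, ranked by loading score, with `out/routes.csv` and
`out/routes.geojson` holding the paths. `out/comparison.csv` lists, per
cell, its EOF top-20% membership and flow class next to its BBAC_I cluster.

The same steps are available as library calls (`simulate_panel`,
`filter_valid_grids`, `fill_gaps`, `compute_anomaly`, `eof_decompose`,
`fit_coclustering`, `infer_routes`, `run_pipeline`) and as YAML-configured
runs (`evacflow run --config cfg.yaml`).

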