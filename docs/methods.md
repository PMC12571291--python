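# Methods

## Data model

The unit of analysis is a *panel*: for each 1 km × 1 km grid cell, two
24-point hourly count series — a pre-disaster baseline weekday and a
post-disaster weekday chosen to match it (same weekday, so the diurnal
cycle cancels in the difference). Counts are hourly device tallies; a
missing cell-hour is an absent record, while an explicit count of 0 is an
observation. Each cell optionally carries a macroseismic intensity label
(VI–IX); zones below VI are outside the analysis domain.

## Quality control and anomalies

1. **Missing-run filter.** A cell is retained only if neither day's series
   contains a run of ≥ `max_run` (default 3) consecutive missing hours.
   The rule is applied per day, and a cell must pass on both days: three
   hours is 12.5% of a day, long enough for post-disaster behaviour to
   change qualitatively, so longer gaps cannot be interpolated safely.
   The validity report separately tallies cells with a fully missing day
   (`n_empty_day`), since a stricter accounting could exclude those from
   the candidate set before filtering; it also reports the excluded
   cells' share of the observed baseline-day population (missing baseline
   hours contribute zero to numerator and denominator).
2. **Gap filling.** Interior gaps are filled linearly between the flanking
   observations; leading/trailing gaps take the nearest observed value
   (linear interpolation is undefined without two flanking points).
   Filling is idempotent and never alters observed values.
3. **Anomaly.** `D_it = P_post,it − P_pre,it` per cell and hour, rows
   ordered by grid id, giving the G×24 anomaly matrix. Zone profiles are
   plain per-zone means of member-cell anomalies.

## EOF decomposition

Each cell's temporal mean is removed (covariance EOF — no per-cell
variance scaling), and the spatial covariance `C = O′O′ᵀ/(T−1)` is
eigendecomposed. Computation runs through a thin SVD of O′, which yields
the same modes and eigenvalues (`λ_j = s_j²/(T−1)`) without forming the
G×G matrix when G ≫ T; a symmetric eigensolve of the explicit covariance
serves as the independent cross-check in the tests. PCs are the raw
projection `O′ᵀ·EOFs` with no unit-variance rescaling, so PC *k*'s sample
variance equals eigenvalue *k* and `modes·pcsᵀ` reconstructs the centred
field exactly at full rank.

Mode/PC sign pairs are jointly arbitrary; the orientation convention makes
each mode's largest-|loading| cell positive. Eigenvalue gaps below 1e−10
(relative) trigger a warning that mode ordering/rotation is unstable. The
"strongest cells" of a mode are the top ⌈qG⌉ by |loading| (default
q = 0.2), ranked per mode with a union convenience wrapper across modes;
their variance share is the fraction of the unit-norm loading mass they
carry. Flow classification uses the raw sign product of loading and PC
with a dead-band of 0 by default.

**Reading flow "during" an event window.** A persistent depletion signal
sits *above* its daily mean early in the window and *below* it late, so
the raw sign rule applied at the window's opening hours reads "increase"
for cells that are in fact about to drain. The package's convention — used
in the recovery checks and the acceptance script — evaluates the flow
class at the final hour of the evacuation window, when the displacement is
fully expressed.

## BBAC_I

Min-max scaling is global over the matrix (not per row), preserving
magnitude separation between cells; a constant matrix maps to zeros with a
warning. The loss is the I-divergence between the scaled matrix and its
block-mean approximation, with an epsilon floor of 1e−10 on block means
inside logarithms (scaled data contain exact zeros). An absolute loss
threshold would be scale-dependent, so convergence is judged on the
per-iteration improvement instead: the loop stops when it drops below
`tol` (default 1e−6) or at `max_iterations` (default 100).

Each restart alternates (a) block-mean updates with (b) batch per-row
(and, when tc > 1, per-column) argmin reassignment — both steps are
non-increasing in the loss — followed by a sequential per-item refinement
that evaluates each candidate move on the exact objective via the closed
form `F = Σ x log x − Σ_b S_b log(S_b/n_b)` (block means are the
Bregman-optimal representatives, so the partition loss depends only on
block sums and sizes). The refinement escapes the batch update's local
minima because it accounts for the mean shift a move itself causes. Empty
clusters are repaired by moving in the row with the largest loss
contribution; argmin ties break to the lowest cluster index. The best of
`n_restarts` (default 10) random initialisations is returned. Defaults
`gc = 4`, `tc = 1` reflect the usual spatial-comparison configuration; no
model-selection criterion is applied, `gc` is a configuration knob.

BBAC_I cannot handle negative data, so the pipeline feeds it the raw
(non-negative) disaster-day counts rather than the anomalies.

## Route inference

Origin cores are connected components (8-neighbour lattice adjacency, or a
user-supplied road-edge graph) of the top-q most-negative loadings of an
oriented mode; destination cores likewise for most-positive. For every
graph-connected (origin, destination) pair the minimum-cost path is found
with per-cell cost `1 − |loading|/max|loading|` (invariant to global
rescaling), summed over all path cells via a virtual super-source so the
first cell counts too. All connected pairs are returned, ranked by mean
normalized |loading| along the path; how many are meaningful is
data-dependent, and disconnected pairs are reported as such. This module
is an explicit, deterministic operationalization of what is otherwise an
expert visual-overlay judgement; it makes no claim of road-network realism.

## Synthetic scenario generator

The generator emulates the phenomenology the analysis targets on a 15×20
lattice (300 cells): a 20-cell **source** block in the intensity-IX/VIII
core, a 16-cell **corridor** running east, a 20-cell **shelter** block in
the outer VI band, and **background** elsewhere; intensity zones fall off
with distance from the source core. Defaults (chosen once, as a realistic
mid-sized event):

| parameter | default | meaning |
|---|---|---|
| `baseline_profile` | 160 + 90·sin diurnal | hourly mean counts, night minimum ≈ 70 |
| `evac_start/end_hour` | 1, 13 | evacuation ramp window (h) |
| `evac_fraction` | 0.6 | fraction of source baseline that departs |
| `shelter_lag_hours` | 2 | delay before displaced mass reaches shelters |
| `corridor_transit_peak_hour` | 10 | hour of peak corridor occupancy |
| `corridor_peak_fraction` | 0.5 | peak corridor occupancy as a fraction of peak displaced mass |
| `corridor_sigma_hours` | 2.5 | Gaussian width of the transit bump |
| `noise_dispersion` | 1.0 | Poisson counts; d > 1 over-disperses via d·Poisson(μ/d) |
| `missing_rate` | 0.05 | stationary per-cell-hour outage probability |
| `outage_run_length` | 2.0 | mean consecutive-hour outage length |
| `zone_outage_factor` | 2.0 | outage multiplier in zones VIII/IX |

Sources lose `evac_fraction` of their baseline, ramped linearly over the
window and persisting after it (evacuees do not return the same day);
shelters gain exactly the lagged displaced mass, split evenly — with
`noise_dispersion = 0` the source deficit at hour *t* equals the shelter
surplus at *t* + lag, and a displaced mass exceeding the shelter capacity
model (`shelter_capacity_multiplier` × peak baseline per shelter cell) is
rejected. The corridor bump is a Gaussian in time that returns to baseline
at the day's edges. Missingness comes from a stationary two-state Markov
chain (geometric run lengths), so the ≥3-run filter sees both sub- and
supra-threshold runs, with the outage rate doubled in the highest-intensity
zones to emulate damage-correlated data loss.

What the generator does **not** emulate: road-network geometry, individual
trajectories, gravity/radiation-style destination choice, weekday effects,
multi-day dynamics, or spatially correlated noise. Passing recovery tests
therefore demonstrate that the pipeline detects planted structure of the
stated kind at realistic noise levels — not that it would resolve the far
messier structure of real operator data.

## Problem sizes and numerics

The recovery tests and the acceptance script run the default 300-cell,
24-hour scenario (about 200 cells survive quality control at the default
outage rates); the optimizer-vs-enumeration check uses 100 seeded 8×6
instances with gc = 3 (3⁸ partitions each, evaluated in closed form); the
EOF cross-check uses 50 random G ≤ 30 matrices; the route oracle uses a
400-cell lattice against an independent sparse-graph Dijkstra. Everything
is driven by explicit seeds through `numpy.random.Generator` — no global
RNG state — and a fixed configuration and seed reproduce byte-identical
pipeline outputs (floats written at 10 significant digits).

## Known limitations

- Two observation days only: anomalies conflate the disaster signal with
  any residual day-to-day variability.
- The missing-run filter preferentially removes the hardest-hit cells
  (outages correlate with damage), so surviving-cell summaries understate
  impact in the worst zones; the validity report quantifies what was
  dropped but no correction is attempted.
- EOF modes are orthogonal by construction; physically distinct processes
  that overlap in space/time mix into shared modes, and near-degenerate
  eigenvalues make individual modes unstable (a warning is raised).
- BBAC_I with tc = 1 depends on the data only through row sums over
  column clusters; cells with similar totals but different shapes can land
  in one cluster.
- Route inference assumes movement along the lattice (or the supplied
  graph) and has no capacity, timing, or traffic model.
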