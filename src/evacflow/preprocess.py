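"""Quality control, gap filling, anomaly derivation, and zone summaries.

The pipeline mirrors standard operator-data preprocessing for two matched
weekdays: drop cells whose series contain long consecutive outages, fill
the remaining short gaps by linear interpolation, difference the two days
per cell and hour (the population anomaly), and summarise anomalies by
macroseismic intensity zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import HOURS, INTENSITY_ZONES, AnomalyMatrix, GridPanel


@dataclass
class ValidityReport:
    """Accounting of the missing-run filter.

    ``invalid_population_share`` is the excluded cells' share of the total
    observed baseline-day population (missing baseline hours contribute
    zero to both numerator and denominator). ``n_empty_day`` counts cells
    with at least one fully missing day, reported separately because such
    cells could equally be treated as never having entered the candidate
    set.
    """

    n_total: int
    n_valid: int
    n_invalid: int
    valid_fraction: float
    invalid_population_share: float
    n_empty_day: int
    rejection_reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_valid + self.n_invalid == self.n_total
        assert 0.0 <= self.valid_fraction <= 1.0
        assert 0.0 <= self.invalid_population_share <= 1.0


@dataclass
class ZoneProfile:
    """Hourly mean anomaly and cell count per intensity zone."""

    zones: list[str]
    mean_anomaly: np.ndarray  # (n_zones, 24)
    grid_counts: np.ndarray  # (n_zones,)


def longest_missing_run(series: np.ndarray) -> int:
    """Length of the longest consecutive-NaN run in a 1-D series."""
    miss = np.isnan(np.asarray(series, dtype=float))
    if not miss.any():
        return 0
    # Run-length encode the missingness indicator.
    edges = np.flatnonzero(np.diff(np.concatenate(([0], miss.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    return int((stops - starts).max())


def filter_valid_grids(
    panel: GridPanel, max_run: int = 3
) -> tuple[GridPanel, ValidityReport]:
    """Drop cells with any missing run of length >= ``max_run`` on either day.

    The run criterion is applied per day (each 24-point series separately),
    and a cell must pass on both days to be retained. Cells with a fully
    missing day necessarily fail and are tallied in ``n_empty_day``.
    """
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    if panel.n_grids == 0:
        raise ValueError("cannot filter an empty panel")

    keep = np.ones(panel.n_grids, dtype=bool)
    reasons: dict[str, str] = {}
    n_empty_day = 0
    for i, gid in enumerate(panel.grid_ids):
        parts = []
        empty = False
        for day, series in (("pre", panel.pre[i]), ("post", panel.post[i])):
            run = longest_missing_run(series)
            if np.isnan(series).all():
                empty = True
            if run >= max_run:
                parts.append(f"missing run of {run} h on {day} day")
        if empty:
            n_empty_day += 1
        if parts:
            keep[i] = False
            reasons[str(gid)] = "; ".join(parts)

    pre_obs = np.nan_to_num(panel.pre, nan=0.0)
    total_pop = pre_obs.sum()
    invalid_pop = pre_obs[~keep].sum()
    report = ValidityReport(
        n_total=panel.n_grids,
        n_valid=int(keep.sum()),
        n_invalid=int((~keep).sum()),
        valid_fraction=float(keep.mean()),
        invalid_population_share=float(invalid_pop / total_pop) if total_pop > 0 else 0.0,
        n_empty_day=n_empty_day,
        rejection_reasons=reasons,
    )
    if report.n_valid == 0:
        warnings.warn("all grids rejected by the missing-run filter", stacklevel=2)
    return panel.subset(keep), report


def _fill_series(series: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(series)
    if not obs.any():
        raise ValueError("cannot fill a series with zero observed values")
    if obs.all():
        return series.copy()
    t = np.arange(len(series), dtype=float)
    # np.interp is linear between flanking observations and clamps to the
    # nearest observed value beyond the ends (the boundary rule).
    return np.interp(t, t[obs], series[obs])


def fill_gaps(panel: GridPanel) -> GridPanel:
    """Fill missing hours: linear interpolation inside, nearest value at ends.

    Observed values are left unchanged; the result has no missing entries.
    Idempotent.
    """
    pre = np.empty_like(panel.pre)
    post = np.empty_like(panel.post)
    for i in range(panel.n_grids):
        pre[i] = _fill_series(panel.pre[i])
        post[i] = _fill_series(panel.post[i])
    return GridPanel(
        grid_ids=panel.grid_ids.copy(),
        lon=panel.lon.copy(),
        lat=panel.lat.copy(),
        zone=panel.zone.copy(),
        pre=pre,
        post=post,
    )


def compute_anomaly(panel: GridPanel) -> AnomalyMatrix:
    """Population anomaly D_it = P_post,it − P_pre,it, sorted by grid id."""
    if np.isnan(panel.pre).any() or np.isnan(panel.post).any():
        raise ValueError("panel must be gap-filled before computing anomalies")
    p = panel.sorted_by_id()
    return AnomalyMatrix(values=p.post - p.pre, grid_index=p.grid_ids)


def zone_profiles(
    anom: AnomalyMatrix, zones: dict[str, str] | np.ndarray
) -> ZoneProfile:
    """Hourly mean anomaly per intensity zone (zones VI and above only).

    ``zones`` maps grid_id -> zone label (or is an array aligned with
    ``anom.grid_index``). Cells outside VI..IX are excluded; empty zones
    are omitted with a warning.
    """
    if isinstance(zones, dict):
        labels = np.array([zones[str(g)] for g in anom.grid_index], dtype=object)
    else:
        labels = np.asarray(zones, dtype=object)
        if labels.shape != (anom.n_grids,):
            raise ValueError("zone labels must align with the anomaly grid index")

    kept_zones, means, counts = [], [], []
    for z in INTENSITY_ZONES:
        mask = labels == z
        if not mask.any():
            warnings.warn(f"intensity zone {z} has no grids; omitted", stacklevel=2)
            continue
        kept_zones.append(z)
        means.append(anom.values[mask].mean(axis=0))
        counts.append(int(mask.sum()))
    outside = ~np.isin(labels.astype(str), INTENSITY_ZONES)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} grids outside zones VI-IX excluded from profiles",
            stacklevel=2,
        )
    return ZoneProfile(
        zones=kept_zones,
        mean_anomaly=np.array(means) if means else np.empty((0, HOURS)),
        grid_counts=np.array(counts, dtype=int),
    )
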