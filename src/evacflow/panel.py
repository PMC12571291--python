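"""Core in-memory containers for grid-aggregated population panels.

A *panel* holds, for every 1 km × 1 km grid cell, two 24-hour series of
hourly population counts: a pre-disaster baseline day and a post-disaster
day. Missing cell-hours are encoded as NaN. The anomaly matrix is the
per-cell, per-hour difference D_it = P_post,it − P_pre,it, which removes
the diurnal cycle and isolates disaster-attributable change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HOURS = 24

#: Ordinal macroseismic intensity classes considered exposed to damage.
INTENSITY_ZONES = ("VI", "VII", "VIII", "IX")


@dataclass
class GridPanel:
    """Per-grid hourly count series for two matched days.

    Attributes
    ----------
    grid_ids : (G,) array of str
        Unique cell identifiers.
    lon, lat : (G,) float arrays
        Degrees of the cell centers.
    zone : (G,) array of str
        Macroseismic intensity label per cell ("VI".."IX") or "unknown".
    pre, post : (G, 24) float arrays
        Hourly counts for the baseline and disaster day; NaN marks a
        missing cell-hour (an observed count of 0 is a valid value).
    """

    grid_ids: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    zone: np.ndarray
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        self.grid_ids = np.asarray(self.grid_ids, dtype=object)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.zone = np.asarray(self.zone, dtype=object)
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        self.validate()

    @property
    def n_grids(self) -> int:
        return len(self.grid_ids)

    def validate(self) -> None:
        g = self.n_grids
        if len(set(self.grid_ids)) != g:
            raise ValueError("grid_ids must be unique")
        for name in ("lon", "lat", "zone"):
            if getattr(self, name).shape != (g,):
                raise ValueError(f"{name} must have shape ({g},)")
        for name in ("pre", "post"):
            arr = getattr(self, name)
            if arr.shape != (g, HOURS):
                raise ValueError(f"{name} must have shape ({g}, {HOURS})")
            obs = arr[~np.isnan(arr)]
            if obs.size and (not np.all(np.isfinite(obs)) or np.any(obs < 0)):
                raise ValueError(f"observed counts in {name} must be finite and >= 0")

    def subset(self, mask: np.ndarray) -> "GridPanel":
        """Return a new panel restricted to the cells selected by ``mask``."""
        return GridPanel(
            grid_ids=self.grid_ids[mask],
            lon=self.lon[mask],
            lat=self.lat[mask],
            zone=self.zone[mask],
            pre=self.pre[mask],
            post=self.post[mask],
        )

    def sorted_by_id(self) -> "GridPanel":
        order = np.argsort(self.grid_ids.astype(str), kind="stable")
        return self.subset(order)


@dataclass
class AnomalyMatrix:
    """G×T matrix of post-minus-pre population differences.

    Built only from valid, gap-filled cells, so it contains no missing
    entries. Rows follow ``grid_index`` (sorted grid ids), columns
    ``hour_index`` (0..23).
    """

    values: np.ndarray
    grid_index: np.ndarray
    hour_index: np.ndarray = field(default_factory=lambda: np.arange(HOURS))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid_index = np.asarray(self.grid_index, dtype=object)
        self.hour_index = np.asarray(self.hour_index, dtype=int)
        if self.values.shape != (len(self.grid_index), len(self.hour_index)):
            raise ValueError("values shape inconsistent with grid/hour indices")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("anomaly matrix must have no missing entries")

    @property
    def n_grids(self) -> int:
        return self.values.shape[0]

    @property
    def n_hours(self) -> int:
        return self.values.shape[1]
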