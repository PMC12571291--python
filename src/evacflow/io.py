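"""CSV/GeoJSON readers and writers, pipeline configuration, orchestration.

The on-disk panel schema is one row per observed cell-hour:

    grid_id, lon, lat, zone, day, hour, count

with ``day`` in {pre, post} and ``hour`` in 0–23; a missing cell-hour is an
absent row (an explicit count of 0 is an observation). Alternatively a
``timestamp`` column (ISO-8601) may replace ``day``/``hour``: the earlier
of the two dates present is the baseline day, the later the disaster day.

All artifacts are written as UTF-8 CSV (floats at 10 significant digits)
with a ``#``-comment header stamping the configuration and seed, so a
fixed config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bbac, eof, preprocess, routes
from .panel import HOURS, AnomalyMatrix, GridPanel

logger = logging.getLogger("evacflow")

FLOAT_FMT = "%.10g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# Panel CSV


def read_panel_csv(path: str | Path) -> GridPanel:
    """Read the long-format panel CSV into a :class:`GridPanel`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel CSV not found: {path}")
    df = pd.read_csv(path, comment="#", dtype={"grid_id": str})
    if "timestamp" in df.columns and "day" not in df.columns:
        ts = pd.to_datetime(df["timestamp"])
        dates = np.sort(ts.dt.date.unique())
        if len(dates) != 2:
            raise ValueError(
                f"timestamp column must contain exactly 2 dates, found {len(dates)}"
            )
        df = df.assign(
            day=np.where(ts.dt.date == dates[0], "pre", "post"), hour=ts.dt.hour
        )
    required = {"grid_id", "lon", "lat", "zone", "day", "hour", "count"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"panel CSV missing columns: {sorted(missing_cols)}")

    bad_day = ~df["day"].isin(["pre", "post"])
    if bad_day.any():
        raise ValueError(f"bad day value at row {int(np.flatnonzero(bad_day)[0])}")
    bad_hour = (df["hour"] < 0) | (df["hour"] >= HOURS)
    if bad_hour.any():
        raise ValueError(f"hour out of range at row {int(np.flatnonzero(bad_hour)[0])}")
    bad_count = ~np.isfinite(df["count"]) | (df["count"] < 0)
    if bad_count.any():
        raise ValueError(f"bad count at row {int(np.flatnonzero(bad_count)[0])}")

    meta = df.groupby("grid_id", sort=True).first()[["lon", "lat", "zone"]]
    ids = meta.index.to_numpy(dtype=object)
    idx = {g: i for i, g in enumerate(ids)}
    pre = np.full((len(ids), HOURS), np.nan)
    post = np.full((len(ids), HOURS), np.nan)
    for gid, day, hour, count in zip(df["grid_id"], df["day"], df["hour"], df["count"]):
        (pre if day == "pre" else post)[idx[gid], int(hour)] = count
    return GridPanel(
        grid_ids=ids,
        lon=meta["lon"].to_numpy(),
        lat=meta["lat"].to_numpy(),
        zone=meta["zone"].to_numpy(dtype=object),
        pre=pre,
        post=post,
    )


def write_panel_csv(panel: GridPanel, path: str | Path, header: str = "") -> None:
    """Write a panel in the long schema; missing cell-hours are omitted."""
    rows = []
    for i, gid in enumerate(panel.grid_ids):
        for day, series in (("pre", panel.pre[i]), ("post", panel.post[i])):
            for h in range(HOURS):
                if not np.isnan(series[h]):
                    rows.append(
                        (gid, _fmt(panel.lon[i]), _fmt(panel.lat[i]), panel.zone[i],
                         day, h, _fmt(series[h]))
                    )
    df = pd.DataFrame(
        rows, columns=["grid_id", "lon", "lat", "zone", "day", "hour", "count"]
    )
    _write_csv(df, path, header)


def write_roles_csv(roles: dict[str, str], path: str | Path, header: str = "") -> None:
    df = pd.DataFrame(sorted(roles.items()), columns=["grid_id", "role"])
    _write_csv(df, path, header)


def _write_csv(df: pd.DataFrame, path: str | Path, header: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Artifact writers


def write_validity_report(
    report: preprocess.ValidityReport, path: str | Path, header: str = ""
) -> None:
    summary = pd.DataFrame(
        {
            "n_total": [report.n_total],
            "n_valid": [report.n_valid],
            "n_invalid": [report.n_invalid],
            "n_empty_day": [report.n_empty_day],
            "valid_fraction": [_fmt(report.valid_fraction)],
            "invalid_population_share": [_fmt(report.invalid_population_share)],
        }
    )
    _write_csv(summary, path, header)
    reasons = pd.DataFrame(
        sorted(report.rejection_reasons.items()), columns=["grid_id", "reason"]
    )
    _write_csv(reasons, Path(path).with_suffix(".reasons.csv"), header)


def write_zone_profiles(
    profile: preprocess.ZoneProfile, path: str | Path, header: str = ""
) -> None:
    rows = []
    for zi, zone in enumerate(profile.zones):
        for h in range(HOURS):
            rows.append((zone, h, _fmt(profile.mean_anomaly[zi, h]),
                         profile.grid_counts[zi]))
    df = pd.DataFrame(rows, columns=["zone", "hour", "mean_anomaly", "n_grids"])
    _write_csv(df, path, header)


def write_anomaly_wide(anom: AnomalyMatrix, path: str | Path, header: str = "") -> None:
    df = pd.DataFrame(
        {f"h{h:02d}": [_fmt(v) for v in anom.values[:, i]]
         for i, h in enumerate(anom.hour_index)},
    )
    df.insert(0, "grid_id", anom.grid_index)
    _write_csv(df, path, header)


def read_anomaly_wide(path: str | Path) -> AnomalyMatrix:
    df = pd.read_csv(path, comment="#", dtype={"grid_id": str})
    hours = [c for c in df.columns if c.startswith("h")]
    return AnomalyMatrix(
        values=df[hours].to_numpy(dtype=float),
        grid_index=df["grid_id"].to_numpy(dtype=object),
        hour_index=np.array([int(c[1:]) for c in hours]),
    )


def write_eof_result(result: eof.EOFResult, out_dir: str | Path, header: str = "") -> None:
    out = Path(out_dir)
    modes = pd.DataFrame(
        {f"mode{j + 1}": [_fmt(v) for v in result.modes[:, j]] for j in range(result.k)}
    )
    modes.insert(0, "grid_id", result.grid_index)
    _write_csv(modes, out / "eof_modes.csv", header)
    pcs = pd.DataFrame(
        {f"pc{j + 1}": [_fmt(v) for v in result.pcs[:, j]] for j in range(result.k)}
    )
    pcs.insert(0, "hour", np.arange(result.pcs.shape[0]))
    _write_csv(pcs, out / "eof_pcs.csv", header)
    summary = pd.DataFrame(
        {
            "mode": np.arange(1, result.k + 1),
            "eigenvalue": [_fmt(v) for v in result.eigenvalues],
            "explained_fraction": [_fmt(v) for v in result.explained_fraction],
        }
    )
    _write_csv(summary, out / "eof_summary.csv", header)


def write_loadings_geojson(
    result: eof.EOFResult, lon: np.ndarray, lat: np.ndarray, path: str | Path
) -> None:
    features = []
    for i, gid in enumerate(result.grid_index):
        props = {"grid_id": str(gid)}
        for j in range(result.k):
            props[f"mode{j + 1}"] = float(result.modes[i, j])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(lon[i]), float(lat[i])]},
                "properties": props,
            }
        )
    _write_json({"type": "FeatureCollection", "features": features}, path)


def write_cocluster(
    result: bbac.CoClusterResult,
    grid_index: np.ndarray,
    out_dir: str | Path,
    header: str = "",
) -> None:
    out = Path(out_dir)
    labels = pd.DataFrame({"grid_id": grid_index, "cluster": result.row_labels})
    _write_csv(labels, out / "bbac_labels.csv", header)
    traj = pd.DataFrame(
        {
            "iteration": np.arange(len(result.loss_trajectory)),
            "loss": [_fmt(v) for v in result.loss_trajectory],
        }
    )
    _write_csv(traj, out / "bbac_loss.csv", header)
    means = pd.DataFrame(
        {f"tc{j}": [_fmt(v) for v in result.block_means[:, j]]
         for j in range(result.block_means.shape[1])}
    )
    means.insert(0, "row_cluster", np.arange(result.block_means.shape[0]))
    _write_csv(means, out / "bbac_block_means.csv", header)


def write_routes_csv(route_set: routes.RouteSet, path: str | Path, header: str = "") -> None:
    rows = []
    for ri, r in enumerate(route_set.routes):
        for step, gid in enumerate(r.path):
            rows.append((ri, r.origin_core, r.destination_core, step, gid,
                         _fmt(r.cost), _fmt(r.score)))
    df = pd.DataFrame(
        rows,
        columns=["route", "origin_core", "destination_core", "step", "grid_id",
                 "cost", "score"],
    )
    _write_csv(df, path, header)


def write_routes_geojson(
    route_set: routes.RouteSet,
    coords: dict[str, tuple[float, float]],
    path: str | Path,
) -> None:
    features = []
    for ri, r in enumerate(route_set.routes):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(coords[g]) for g in r.path],
                },
                "properties": {
                    "route": ri,
                    "origin_core": r.origin_core,
                    "destination_core": r.destination_core,
                    "cost": r.cost,
                    "score": r.score,
                },
            }
        )
    _write_json({"type": "FeatureCollection", "features": features}, path)


def _write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_road_edges(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, comment="#", dtype=str)
    if not {"grid_id_a", "grid_id_b"} <= set(df.columns):
        raise ValueError("road edge CSV needs columns grid_id_a, grid_id_b")
    return list(zip(df["grid_id_a"], df["grid_id_b"]))


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Everything the one-command pipeline needs; YAML keys are identical."""

    panel_csv: str
    out_dir: str
    zone_csv: str | None = None
    road_edges_csv: str | None = None
    max_run: int = 3
    k: int = 2
    q: float = 0.2
    gc: int = 4
    tc: int = 1
    max_iterations: int = 100
    tol: float = 1e-6
    n_restarts: int = 10
    dead_band: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")
        if not 0.0 < self.q <= 1.0:
            raise ValueError("q must lie in (0, 1]")
        for name in ("k", "gc", "tc", "max_iterations", "n_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tol <= 0 or self.dead_band < 0:
            raise ValueError("tol must be > 0 and dead_band >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def stamp(self) -> str:
        pairs = ", ".join(f"{k}={v}" for k, v in asdict(self).items())
        return f"evacflow pipeline\n{pairs}"


def lattice_positions_from_coords(
    grid_ids: np.ndarray, lon: np.ndarray, lat: np.ndarray
) -> dict[str, tuple[int, int]]:
    """Recover integer (row, col) lattice indices from cell-center coords.

    Rows increase southwards, columns eastwards; spacing is the median
    nearest-neighbour step along each axis.
    """

    def steps(values: np.ndarray) -> float:
        uniq = np.unique(values)
        if len(uniq) < 2:
            return 1.0
        return float(np.median(np.diff(uniq)))

    dlon, dlat = steps(lon), steps(lat)
    col = np.rint((lon - lon.min()) / dlon).astype(int)
    row = np.rint((lat.max() - lat) / dlat).astype(int)
    return {str(g): (int(r), int(c)) for g, r, c in zip(grid_ids, row, col)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run preprocess → EOF → BBAC_I → routes and write the report bundle.

    Fails fast (before any output is written) on unreadable inputs or
    out-of-range parameters. Returns the in-memory artifacts.
    """
    config.validate()
    panel = read_panel_csv(config.panel_csv)
    road_edges = read_road_edges(config.road_edges_csv) if config.road_edges_csv else None
    if config.zone_csv:
        zmap = pd.read_csv(config.zone_csv, comment="#", dtype=str)
        zdict = dict(zip(zmap["grid_id"], zmap["zone"]))
        panel.zone = np.array(
            [zdict.get(str(g), z) for g, z in zip(panel.grid_ids, panel.zone)],
            dtype=object,
        )
    header = config.stamp()
    out = Path(config.out_dir)

    logger.info("preprocess: %d candidate grids", panel.n_grids)
    valid, report = preprocess.filter_valid_grids(panel, max_run=config.max_run)
    filled = preprocess.fill_gaps(valid)
    anom = preprocess.compute_anomaly(filled)
    logger.info("preprocess: %d valid grids (%.1f%%)", report.n_valid,
                100 * report.valid_fraction)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile = preprocess.zone_profiles(
            anom, dict(zip(filled.grid_ids.astype(str), filled.zone))
        )

    k = min(config.k, min(anom.n_grids, anom.n_hours))
    result = eof.orient_signs(eof.eof_decompose(anom, k=k))
    logger.info("eof: explained fractions %s",
                np.round(result.explained_fraction, 3))

    # BBAC_I runs on the raw (non-negative) disaster-day counts.
    sorted_panel = filled.sorted_by_id()
    scaled = bbac.scale_minmax(sorted_panel.post)
    cocluster = bbac.fit_coclustering(
        scaled,
        gc=min(config.gc, anom.n_grids),
        tc=config.tc,
        max_iterations=config.max_iterations,
        tol=config.tol,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )
    logger.info("bbac: final loss %.6g after %d iterations", cocluster.loss,
                cocluster.n_iter)

    route_mode = 1 if k >= 2 else 0
    if road_edges is not None:
        adjacency = routes.adjacency_from_edges(road_edges)
    else:
        positions = lattice_positions_from_coords(
            sorted_panel.grid_ids, sorted_panel.lon, sorted_panel.lat
        )
        adjacency = routes.lattice_adjacency(positions)
    loadings = result.modes[:, route_mode]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cores = routes.extract_polarity_cores(
            result.grid_index, loadings, adjacency, q=config.q
        )
        route_set = routes.infer_routes(cores, result.grid_index, loadings, adjacency)
    logger.info("routes: %d routes, %d unconnected pairs", len(route_set.routes),
                len(route_set.unconnected))

    comparison = build_comparison(result, cocluster, config)

    write_validity_report(report, out / "validity_report.csv", header)
    write_zone_profiles(profile, out / "zone_profiles.csv", header)
    write_anomaly_wide(anom, out / "anomaly.csv", header)
    write_eof_result(result, out, header)
    coords = {
        str(g): (float(lo), float(la))
        for g, lo, la in zip(sorted_panel.grid_ids, sorted_panel.lon, sorted_panel.lat)
    }
    write_loadings_geojson(result, sorted_panel.lon, sorted_panel.lat,
                           out / "eof_loadings.geojson")
    write_cocluster(cocluster, anom.grid_index, out, header)
    write_routes_csv(route_set, out / "routes.csv", header)
    write_routes_geojson(route_set, coords, out / "routes.geojson")
    _write_csv(comparison, out / "comparison.csv", header)

    return {
        "panel": filled,
        "report": report,
        "anomaly": anom,
        "zone_profile": profile,
        "eof": result,
        "cocluster": cocluster,
        "routes": route_set,
        "comparison": comparison,
    }


def build_comparison(
    result: eof.EOFResult, cocluster: bbac.CoClusterResult, config: PipelineConfig
) -> pd.DataFrame:
    """Per-grid EOF vs BBAC_I table: top-fraction membership, flow class, cluster.

    Flow class per mode is evaluated at the hour where |PC| peaks.
    """
    frame: dict[str, object] = {"grid_id": result.grid_index}
    for j in range(result.k):
        top, _ = eof.select_top_loadings(result, j, config.q)
        top_set = {str(g) for g in top}
        peak_hour = int(np.argmax(np.abs(result.pcs[:, j])))
        pc = result.pcs[peak_hour, j]
        frame[f"mode{j + 1}_loading"] = [_fmt(v) for v in result.modes[:, j]]
        frame[f"mode{j + 1}_top{int(100 * config.q)}pct"] = [
            str(g) in top_set for g in result.grid_index
        ]
        frame[f"mode{j + 1}_flow"] = [
            eof.classify_flow(v, pc, config.dead_band) for v in result.modes[:, j]
        ]
    frame["bbac_cluster"] = cocluster.row_labels
    return pd.DataFrame(frame)
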