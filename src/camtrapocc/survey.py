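"""Camera-trap survey ingestion: records, stations, detection histories.

The observable unit throughout the package is the detection history — a
sites × occasions matrix of detected (1) / not detected (0) / not surveyed
(missing) values, paired with a per-cell effort matrix counting the days a
camera was active within each occasion.  Records are photographic events
(station, species, timestamp); they are reduced to at most one independent
detection per station, species and calendar day before histories are built.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

log = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

RECORD_COLUMNS = ["station_id", "species", "timestamp"]
STATION_COLUMNS = [
    "station_id", "x", "y", "coord_system",
    "activation_date", "retrieval_date", "pir_delay_class", "block_id",
]


def read_stations(path) -> pd.DataFrame:
    """Read a station table CSV and validate its invariants."""
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"station table missing columns: {missing}")
    if df["station_id"].duplicated().any():
        dup = df.loc[df["station_id"].duplicated(), "station_id"].iloc[0]
        raise ValueError(f"duplicate station_id: {dup!r}")
    systems = df["coord_system"].unique()
    if len(systems) > 1:
        raise ValueError(f"inconsistent coord_system values: {list(systems)}")
    if systems.size and systems[0] not in ("planar", "lonlat"):
        raise ValueError(f"coord_system must be 'planar' or 'lonlat', got {systems[0]!r}")
    df["activation_date"] = pd.to_datetime(df["activation_date"]).dt.normalize()
    df["retrieval_date"] = pd.to_datetime(df["retrieval_date"]).dt.normalize()
    bad = df["activation_date"] > df["retrieval_date"]
    if bad.any():
        raise ValueError(
            f"activation after retrieval for station {df.loc[bad, 'station_id'].iloc[0]!r}"
        )
    return df.reset_index(drop=True)


def read_records(path, stations: pd.DataFrame) -> pd.DataFrame:
    """Read a record CSV (station_id, species, timestamp).

    Records falling outside their station's [activation, retrieval] window
    are dropped with a warning; unknown stations and unparseable timestamps
    are errors.  Returns a frame with a ``n_dropped`` attribute in
    ``df.attrs``.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "species": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    known = set(stations["station_id"])
    unknown = set(df["station_id"]) - known
    if unknown:
        raise ValueError(f"unknown station_id in records: {sorted(unknown)[0]!r}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(f"unparseable timestamp at row {row + 2} (1-based, incl. header)")
    df = df.assign(timestamp=ts)
    windows = stations.set_index("station_id")[["activation_date", "retrieval_date"]]
    act = df["station_id"].map(windows["activation_date"])
    ret = df["station_id"].map(windows["retrieval_date"])
    day = df["timestamp"].dt.normalize()
    inside = (day >= act) & (day <= ret)
    n_dropped = int((~inside).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} record(s) outside station deployment windows",
            stacklevel=2,
        )
    out = df.loc[inside].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def pool_guild(records: pd.DataFrame, label_map: dict) -> pd.DataFrame:
    """Relabel species into pooled guild classes (e.g. a single
    killers/predators class, or all small mammals pooled as prey).

    The map may be partial; unmapped labels pass through unchanged.  Pooling
    is applied *before* independence filtering so that a guild detection day
    is any member's record day.
    """
    out = records.copy()
    out["species"] = out["species"].map(lambda s: label_map.get(s, s))
    return out


def filter_independent(records: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one record per (station, species, calendar day).

    Records are pooled over 24-hour calendar-day bins; the earliest record
    of each day is retained.  Idempotent.
    """
    if records.empty:
        return records.copy()
    df = records.sort_values("timestamp", kind="mergesort")
    day = df["timestamp"].dt.normalize()
    keep = ~df.assign(_day=day).duplicated(["station_id", "species", "_day"])
    return df.loc[keep.to_numpy()].reset_index(drop=True)


@dataclass
class DetectionHistory:
    """Sites × occasions detection/non-detection matrix with effort.

    ``matrix`` holds 1.0 (detected), 0.0 (surveyed, not detected) or NaN
    (not surveyed); ``effort`` holds the number of active camera days in
    each occasion cell.  A cell is NaN exactly when its effort is zero.
    """

    species: str
    station_ids: list[str]
    matrix: np.ndarray        # float, values {0.0, 1.0, nan}
    effort: np.ndarray        # int, active days per cell
    occasion_days: int = 7

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.effort = np.asarray(self.effort, dtype=int)
        if self.matrix.shape != self.effort.shape:
            raise ValueError("matrix and effort shapes differ")
        if not np.array_equal(np.isnan(self.matrix), self.effort == 0):
            raise ValueError("matrix is missing exactly where effort is zero")
        vals = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("matrix values must be 0, 1 or missing")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of surveyed cells."""
        return ~np.isnan(self.matrix)

    def n_detections(self) -> int:
        """Occasion-level independent detections (count of 1 cells)."""
        return int(np.nansum(self.matrix))

    def naive_occupancy(self) -> float:
        """Fraction of sites with at least one detection."""
        return float((np.nansum(self.matrix, axis=1) > 0).mean())

    def to_csv(self, history_path, effort_path) -> None:
        cols = [f"occ_{j + 1}" for j in range(self.n_occasions)]
        hist = pd.DataFrame(self.matrix, columns=cols)
        hist.insert(0, "station_id", self.station_ids)
        hist.to_csv(history_path, index=False, na_rep=MISSING_TOKEN,
                    float_format="%.0f")
        eff = pd.DataFrame(self.effort, columns=cols)
        eff.insert(0, "station_id", self.station_ids)
        eff.to_csv(effort_path, index=False)

    @classmethod
    def from_csv(cls, history_path, effort_path, species: str = "",
                 occasion_days: int = 7) -> "DetectionHistory":
        hist = pd.read_csv(history_path, dtype={"station_id": str},
                           na_values=[MISSING_TOKEN], keep_default_na=False)
        eff = pd.read_csv(effort_path, dtype={"station_id": str})
        if list(hist["station_id"]) != list(eff["station_id"]):
            raise ValueError("history and effort station orders differ")
        return cls(
            species=species,
            station_ids=list(hist["station_id"]),
            matrix=hist.drop(columns="station_id").to_numpy(dtype=float),
            effort=eff.drop(columns="station_id").to_numpy(dtype=int),
            occasion_days=occasion_days,
        )


def build_history(records: pd.DataFrame, stations: pd.DataFrame,
                  species: str, occasion_days: int = 7) -> DetectionHistory:
    """Collapse independence-filtered records into a weekly detection history.

    Occasions are consecutive ``occasion_days``-long blocks starting at each
    station's activation date; the final partial block keeps its remaining
    days as effort.  A station detected at deployment day d lands in
    occasion floor((d-1)/occasion_days) (0-based).
    """
    sp = records.loc[records["species"] == species]
    if sp.empty:
        warnings.warn(f"no records for species {species!r}; history is all zeros",
                      stacklevel=2)
    station_ids = list(stations["station_id"])
    deploy_days = (
        (stations["retrieval_date"] - stations["activation_date"]).dt.days + 1
    ).to_numpy()
    n_occ = int(np.ceil(deploy_days.max() / occasion_days))
    n = len(station_ids)
    effort = np.zeros((n, n_occ), dtype=int)
    for i, days in enumerate(deploy_days):
        full, rem = divmod(int(days), occasion_days)
        effort[i, :full] = occasion_days
        if rem:
            effort[i, full] = rem
    matrix = np.where(effort > 0, 0.0, np.nan)
    act = stations.set_index("station_id")["activation_date"]
    idx = {s: i for i, s in enumerate(station_ids)}
    for _, row in sp.iterrows():
        i = idx[row["station_id"]]
        d = (row["timestamp"].normalize() - act[row["station_id"]]).days + 1
        j = (d - 1) // occasion_days
        if 0 <= j < n_occ and effort[i, j] > 0:
            matrix[i, j] = 1.0
    return DetectionHistory(species=species, station_ids=station_ids,
                            matrix=matrix, effort=effort,
                            occasion_days=occasion_days)


def apply_gaps(history: DetectionHistory, gaps: dict[str, list[int]]) -> DetectionHistory:
    """Blank whole occasions (camera theft/failure) for named stations.

    ``gaps`` maps station_id to 0-based occasion indices; the cells become
    missing with zero effort.
    """
    matrix = history.matrix.copy()
    effort = history.effort.copy()
    idx = {s: i for i, s in enumerate(history.station_ids)}
    for sid, occs in gaps.items():
        for j in occs:
            matrix[idx[sid], j] = np.nan
            effort[idx[sid], j] = 0
    return DetectionHistory(history.species, history.station_ids, matrix,
                            effort, history.occasion_days)


def _mcp_area_km2(x: np.ndarray, y: np.ndarray, coord_system: str) -> float:
    """Minimum-convex-polygon area of a station array, in km^2."""
    if len(x) < 3:
        return 0.0
    if coord_system == "lonlat":
        # local equirectangular projection to metres
        lat0 = np.deg2rad(y.mean())
        R = 6_371_000.0
        xm = np.deg2rad(x) * R * np.cos(lat0)
        ym = np.deg2rad(y) * R
    else:
        xm, ym = x, y
    pts = np.column_stack([xm, ym])
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        return 0.0
    return float(ConvexHull(pts).volume) / 1e6  # 2-D hull "volume" is area


@dataclass
class SurveySummary:
    """Per-block and total survey effort and detection summaries."""

    blocks: pd.DataFrame       # one row per block_id + a "total" row
    detections: pd.DataFrame   # rows (block, species): daily & occasion counts
    naive: pd.DataFrame        # per species: sites with detection, naive occupancy

    @property
    def total_trap_nights(self) -> int:
        return int(self.blocks.loc[self.blocks["block_id"] == "total",
                                   "trap_nights"].iloc[0])

    @property
    def total_mcp_km2(self) -> float:
        return float(self.blocks.loc[self.blocks["block_id"] == "total",
                                     "mcp_km2"].iloc[0])

    def occasion_detections(self, species: str) -> int:
        sub = self.detections[(self.detections["species"] == species)
                              & (self.detections["block_id"] == "total")]
        return int(sub["occasion_detections"].iloc[0])

    def daily_detections(self, species: str) -> int:
        sub = self.detections[(self.detections["species"] == species)
                              & (self.detections["block_id"] == "total")]
        return int(sub["daily_detections"].iloc[0])


def summarize_survey(histories: dict[str, DetectionHistory],
                     stations: pd.DataFrame,
                     records: pd.DataFrame | None = None) -> SurveySummary:
    """Survey summary: trap-nights, MCP areas, independent detections.

    ``histories`` maps species label to its DetectionHistory (shared station
    set).  Occasion-level counts come from the histories; daily-level counts
    come from ``records`` (already independence-filtered) when provided.
    Trap-nights are the sum of effort cells.
    """
    blocks = sorted(stations["block_id"].unique())
    station_block = stations.set_index("station_id")["block_id"]
    coord_system = stations["coord_system"].iloc[0] if len(stations) else "planar"

    any_hist = next(iter(histories.values())) if histories else None
    block_rows = []
    for b in [*blocks, "total"]:
        sub = stations if b == "total" else stations[stations["block_id"] == b]
        if any_hist is not None:
            mask = np.array([station_block[s] == b or b == "total"
                             for s in any_hist.station_ids])
            tn = int(any_hist.effort[mask].sum())
        else:
            tn = 0
        block_rows.append({
            "block_id": b,
            "n_active_stations": len(sub),
            "trap_nights": tn,
            "mcp_km2": _mcp_area_km2(sub["x"].to_numpy(dtype=float),
                                     sub["y"].to_numpy(dtype=float),
                                     coord_system) if b != "total" else np.nan,
        })
    blocks_df = pd.DataFrame(block_rows)
    total_mcp = blocks_df.loc[blocks_df["block_id"] != "total", "mcp_km2"].sum()
    blocks_df.loc[blocks_df["block_id"] == "total", "mcp_km2"] = total_mcp

    det_rows, naive_rows = [], []
    for sp, hist in histories.items():
        blk = np.array([station_block[s] for s in hist.station_ids])
        if records is not None:
            rec_sp = records[records["species"] == sp]
            rec_blk = rec_sp["station_id"].map(station_block)
        for b in [*blocks, "total"]:
            mask = np.ones(hist.n_sites, bool) if b == "total" else blk == b
            occ_count = int(np.nansum(hist.matrix[mask]))
            if records is not None:
                daily = int(len(rec_sp) if b == "total" else (rec_blk == b).sum())
            else:
                daily = None
            det_rows.append({"species": sp, "block_id": b,
                             "daily_detections": daily,
                             "occasion_detections": occ_count})
        detected = np.nansum(hist.matrix, axis=1) > 0
        naive_rows.append({"species": sp,
                           "n_sites_with_detection": int(detected.sum()),
                           "naive_occupancy": float(detected.mean()) if hist.n_sites else 0.0})
    det_df = pd.DataFrame(det_rows, columns=["species", "block_id",
                                             "daily_detections",
                                             "occasion_detections"])
    naive_df = pd.DataFrame(naive_rows, columns=["species",
                                                 "n_sites_with_detection",
                                                 "naive_occupancy"])
    return SurveySummary(blocks=blocks_df, detections=det_df, naive=naive_df)
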