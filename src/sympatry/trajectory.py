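"""Relocation-data ingestion and per-animal movement summaries.

A *fix* is one collar relocation (animal id, UTC timestamp, lon/lat, and —
once projected — planar x/y in metres).  A :class:`Trajectory` is the ordered
fix series of one animal-season.  The reader speaks the Movebank CSV dialect
by default ("timestamp", "location-long", "location-lat",
"individual-local-identifier"); other dialects are handled with a user column
mapping.

The only per-animal movement constant needed downstream is ``v_max``, the
maximum observed velocity between consecutive fixes, which scales the time
axis of the time-scaled distance metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateError, RowError, ValidationError
from .projection import TransverseMercator

#: Movebank column names -> canonical names.
MOVEBANK_DIALECT = {
    "timestamp": "t",
    "location-long": "lon",
    "location-lat": "lat",
    "individual-local-identifier": "animal_id",
}

#: Default minimum time separation (s) for a velocity estimate; matches the
#: 5-minute timing jitter of the collar location calculation.
DEFAULT_MIN_DT = 300.0


@dataclass
class Trajectory:
    """Ordered relocation series of one animal-season.

    ``fixes`` holds columns ``t`` (tz-aware UTC), ``lon``, ``lat`` and, after
    projection, ``x``, ``y`` (planar metres).  Timestamps are strictly
    increasing.
    """

    animal_id: str
    fixes: pd.DataFrame
    species: str | None = None
    season: str | None = None
    projection: TransverseMercator | None = None

    def __post_init__(self):
        t = self.fixes["t"]
        if len(t) >= 2 and not t.is_monotonic_increasing:
            self.fixes = self.fixes.sort_values("t").reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.fixes)

    @property
    def t_seconds(self) -> np.ndarray:
        """Fix times as float seconds since the Unix epoch."""
        return self.fixes["t"].astype("int64").to_numpy() / 1e9

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) planar coordinates in metres."""
        if "x" not in self.fixes.columns:
            raise ValidationError(
                f"trajectory {self.animal_id!r} has no planar coordinates; "
                "call project_to_plane first"
            )
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    @property
    def centroid(self) -> tuple[float, float]:
        xy = self.xy
        return float(xy[:, 0].mean()), float(xy[:, 1].mean())

    def with_fixes(self, fixes: pd.DataFrame) -> "Trajectory":
        return replace(self, fixes=fixes.reset_index(drop=True))


@dataclass
class ReadReport:
    """What the reader dropped or collapsed, for the run manifest."""

    n_rows: int = 0
    n_kept: int = 0
    n_duplicates_collapsed: int = 0
    n_missing_coords_dropped: int = 0
    dropped_lines: list = field(default_factory=list)


def read_fix_table(path, dialect: dict | None = None):
    """Read a relocation CSV into one :class:`Trajectory` per animal.

    Parameters
    ----------
    path : str or file-like
        CSV with at least timestamp, longitude, latitude and animal-id
        columns.
    dialect : dict, optional
        Mapping from file column names to the canonical names ``t``, ``lon``,
        ``lat``, ``animal_id`` (and optionally ``species``, ``season``).
        Defaults to the Movebank dialect.

    Returns
    -------
    (list of Trajectory, ReadReport)
        Trajectories sorted by animal id, fixes time-sorted, exact duplicate
        (id, t, lon, lat) rows collapsed, rows with missing coordinates
        dropped and reported.

    Raises
    ------
    ConfigurationError
        A mapped column is absent from the file.
    RowError
        An unparseable timestamp, or two fixes with the same (id, t) but
        different coordinates (ambiguous duplicate); carries the line number.
    """
    dialect = dict(dialect or MOVEBANK_DIALECT)
    df = pd.read_csv(path, dtype={c: str for c in dialect})
    missing = [c for c in dialect if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing column(s) in fix table: {missing}")
    df = df.rename(columns=dialect)[list(dialect.values())]
    # +2: header line plus 1-based indexing.
    df["_line"] = np.arange(len(df)) + 2
    report = ReadReport(n_rows=len(df))

    t = pd.to_datetime(df["t"], utc=True, errors="coerce", format="mixed")
    bad = t.isna() & df["t"].notna()
    if bad.any():
        line = int(df.loc[bad, "_line"].iloc[0])
        raise RowError(f"unparseable timestamp {df.loc[bad, 't'].iloc[0]!r}", line)
    df["t"] = t
    for c in ("lon", "lat"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    miss = df[["t", "lon", "lat", "animal_id"]].isna().any(axis=1)
    if miss.any():
        report.n_missing_coords_dropped = int(miss.sum())
        report.dropped_lines.extend(df.loc[miss, "_line"].astype(int).tolist())
        df = df[~miss]

    n_before = len(df)
    df = df.drop_duplicates(subset=["animal_id", "t", "lon", "lat"])
    report.n_duplicates_collapsed = n_before - len(df)

    ambiguous = df.duplicated(subset=["animal_id", "t"], keep=False)
    if ambiguous.any():
        row = df[ambiguous].iloc[1]
        raise RowError(
            f"animal {row['animal_id']!r} has two fixes at {row['t']} with "
            "different coordinates (ambiguous duplicate)",
            int(row["_line"]),
        )

    if np.any(np.abs(df["lat"]) > 90) or np.any(np.abs(df["lon"]) > 180):
        raise ValidationError("longitude/latitude outside valid range")

    trajectories = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        fixes = grp.sort_values("t")[
            [c for c in ("t", "lon", "lat", "species", "season") if c in grp]
        ].reset_index(drop=True)
        kwargs = {}
        if "species" in fixes:
            kwargs["species"] = fixes.pop("species").iloc[0]
        if "season" in fixes:
            kwargs["season"] = fixes.pop("season").iloc[0]
        trajectories.append(Trajectory(str(animal_id), fixes, **kwargs))
    report.n_kept = int(sum(tr.n for tr in trajectories))
    return trajectories, report


def write_fix_table(trajectories, path, dialect: dict | None = None):
    """Write trajectories back to CSV in the given dialect, with x/y appended."""
    dialect = dict(dialect or MOVEBANK_DIALECT)
    inverse = {v: k for k, v in dialect.items()}
    frames = []
    for tr in trajectories:
        out = tr.fixes.copy()
        out["animal_id"] = tr.animal_id
        out["t"] = out["t"].dt.strftime("%Y-%m-%d %H:%M:%S")
        frames.append(out)
    table = pd.concat(frames, ignore_index=True)
    table = table.rename(columns=inverse)
    table.to_csv(path, index=False)


def project_to_plane(traj: Trajectory, projection: TransverseMercator | None = None) -> Trajectory:
    """Attach planar x/y (metres) to a trajectory.

    Default projection is a transverse Mercator centred on the data centroid
    (mean lon, mean lat), so the track's own centre maps near the origin and
    scale distortion over a <200 km window is negligible.  The transform is
    invertible to better than 1e-6 degrees.
    """
    lon = traj.fixes["lon"].to_numpy(dtype=float)
    lat = traj.fixes["lat"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValidationError("longitude/latitude outside valid range")
    if projection is None:
        projection = TransverseMercator(float(lon.mean()), float(lat.mean()))
    x, y = projection.forward(lon, lat)
    fixes = traj.fixes.copy()
    fixes["x"], fixes["y"] = x, y
    return replace(traj, fixes=fixes, projection=projection)


def compute_vmax(traj: Trajectory, min_dt: float = DEFAULT_MIN_DT) -> float:
    """Maximum observed velocity (m/s) between consecutive fixes.

    Consecutive pairs closer than ``min_dt`` seconds are excluded so timing
    jitter cannot inflate the estimate.

    Raises
    ------
    DegenerateError
        Fewer than 2 fixes, or no pair separated by at least ``min_dt``.
    """
    if min_dt <= 0:
        raise ValidationError("min_dt must be positive")
    if traj.n < 2:
        raise DegenerateError("v_max needs at least 2 fixes")
    xy = traj.xy
    dt = np.diff(traj.t_seconds)
    d = np.hypot(*np.diff(xy, axis=0).T)
    ok = dt >= min_dt
    if not ok.any():
        raise DegenerateError("no consecutive pair with dt >= min_dt; v_max undefined")
    return float(np.max(d[ok] / dt[ok]))
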