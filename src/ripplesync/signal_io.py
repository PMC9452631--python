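"""Containers and I/O for continuous signals, position tracks and result tables.

Conventions used throughout the package:

* all times are absolute seconds from session start (float);
* sample index ``i`` of a trace maps to time ``t0 + i / fs`` exactly;
* event intervals are half-open ``[start, end)``;
* voltages are microvolts, positions centimetres;
* CSV files are comma-separated with ``.`` decimal and a header row for
  multi-column files; HDF5 layout is ``/lfp/<electrode>/samples`` with
  attributes ``fs``, ``region``, ``t0``, ``session_id``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

REGIONS = ("CA1", "MEC")

#: canonical column order of an event table
EVENT_COLUMNS = [
    "session_id",
    "electrode_id",
    "region",
    "start_s",
    "end_s",
    "peak_time_s",
    "duration_ms",
    "amplitude_z",
    "peak_to_trough_uv",
    "mean_power_db",
    "freq_peak_hz",
    "has_sharp_wave",
]


@dataclass(frozen=True)
class LfpTrace:
    """One electrode's continuous extracellular voltage series.

    Parameters
    ----------
    samples : ndarray of float
        Voltage in microvolts, recording order.
    fs : float
        Sampling rate in Hz (nominally 2 kHz for tetrode LFP but always
        carried explicitly).
    t0 : float
        Time of the first sample in seconds from session start.
    region : {"CA1", "MEC"}
    electrode_id, session_id : str
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    region: str = "CA1"
    electrode_id: str = "e0"
    session_id: str = "s0"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise DataValidationError("LFP trace needs at least 2 samples")
        bad = np.flatnonzero(~np.isfinite(samples))
        if bad.size:
            raise DataValidationError(
                f"LFP trace contains non-finite sample at index {bad[0]}"
            )
        if not self.electrode_id:
            raise DataValidationError("electrode_id must be nonempty")
        if self.region not in REGIONS:
            raise DataValidationError(f"region must be one of {REGIONS}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Session duration covered by the trace in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Per-sample timestamps ``t0 + i / fs``."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_at(self, t: float) -> int:
        """Sample index whose half-open interval contains time ``t``."""
        return int(np.floor((t - self.t0) * self.fs))


@dataclass(frozen=True)
class PositionTrack:
    """Head-position samples from the overhead tracking camera (nominal 50 Hz)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs_nominal: float = 50.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, arr in (("times", times), ("x", x), ("y", y)):
            object.__setattr__(self, name, arr)
        if not (times.size == x.size == y.size):
            raise DataValidationError("times, x and y must have equal length")
        if times.size < 2:
            raise DataValidationError("position track needs at least 2 samples")
        if np.any(np.diff(times) <= 0):
            raise DataValidationError("position timestamps must be strictly increasing")
        if self.fs_nominal <= 0:
            raise ConfigError("fs_nominal must be positive")

    @property
    def n_samples(self) -> int:
        return self.times.size


def empty_event_table() -> pd.DataFrame:
    """Header-only event table with the canonical columns."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in EVENT_COLUMNS})
    return df.astype(
        {
            "start_s": float,
            "end_s": float,
            "peak_time_s": float,
            "duration_ms": float,
            "amplitude_z": float,
            "peak_to_trough_uv": float,
            "mean_power_db": float,
            "freq_peak_hz": float,
            "has_sharp_wave": bool,
        }
    )


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of an event table.

    Events must be sorted by peak time within each electrode and no two
    events of one electrode may overlap in ``[start, end)``.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise DataValidationError(f"event table missing columns: {missing}")
    for _, grp in events.groupby("electrode_id", sort=False):
        peaks = grp["peak_time_s"].to_numpy()
        if np.any(np.diff(peaks) < 0):
            raise DataValidationError(
                "events must be sorted by peak time within an electrode"
            )
        starts = grp["start_s"].to_numpy()
        ends = grp["end_s"].to_numpy()
        if len(grp) > 1 and np.any(starts[1:] < ends[:-1]):
            raise DataValidationError("overlapping events within one electrode")
    return events


def read_lfp(
    path: str | Path,
    *,
    fs: float | None = None,
    region: str = "CA1",
    electrode_id: str = "e0",
    session_id: str = "s0",
    t0: float = 0.0,
) -> LfpTrace:
    """Load one electrode's LFP from CSV or HDF5.

    CSV may be a bare column of values (``fs`` must then be given) or two
    columns ``time,value`` from which ``fs`` and ``t0`` are inferred.  The
    HDF5 layout is ``/lfp/<electrode>/samples`` with attributes ``fs``,
    ``region`` and optional ``t0``, ``session_id`` and ``scale_uv_per_bit``
    (applied multiplicatively on read).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            grp = f["lfp"][electrode_id]
            ds = grp["samples"]
            raw = np.asarray(ds[...], dtype=float)
            scale = float(ds.attrs.get("scale_uv_per_bit", grp.attrs.get("scale_uv_per_bit", 1.0)))
            fs_file = float(ds.attrs.get("fs", grp.attrs.get("fs", fs or 0.0)))
            region = str(ds.attrs.get("region", grp.attrs.get("region", region)))
            t0 = float(ds.attrs.get("t0", grp.attrs.get("t0", t0)))
            session_id = str(ds.attrs.get("session_id", grp.attrs.get("session_id", session_id)))
        if fs_file <= 0:
            raise ConfigError("HDF5 trace declares no positive sampling rate")
        samples = raw * scale
        fs = fs_file
    else:
        df = pd.read_csv(path)
        if df.shape[1] == 1:
            if fs is None or fs <= 0:
                raise ConfigError("value-only CSV requires a positive declared fs")
            samples = df.iloc[:, 0].to_numpy(dtype=float)
        else:
            t = df.iloc[:, 0].to_numpy(dtype=float)
            samples = df.iloc[:, 1].to_numpy(dtype=float)
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise DataValidationError("time column must be strictly increasing")
            fs = 1.0 / float(np.median(dt))
            t0 = float(t[0])
    bad = np.flatnonzero(~np.isfinite(samples))
    if bad.size:
        raise DataValidationError(f"non-finite sample at row {bad[0]}")
    return LfpTrace(
        samples=samples,
        fs=float(fs),
        t0=t0,
        region=region,
        electrode_id=electrode_id,
        session_id=session_id,
    )


def read_position(path: str | Path) -> PositionTrack:
    """Load a position track from CSV.

    Accepts ``time,x,y`` (single tracked point) or ``time,x1,y1,x2,y2``
    (two head-stage LEDs).  Two-LED files are reduced to a single head
    position by taking the midpoint; rows where either LED is missing are
    dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if {"time", "x1", "y1", "x2", "y2"}.issubset(cols):
        n_in = len(df)
        valid = df[["x1", "y1", "x2", "y2"]].notna().all(axis=1)
        dropped = int(n_in - valid.sum())
        if dropped:
            logger.warning("read_position: dropped %d/%d rows with a missing LED", dropped, n_in)
        df = df.loc[valid]
        x = (df["x1"].to_numpy(float) + df["x2"].to_numpy(float)) / 2.0
        y = (df["y1"].to_numpy(float) + df["y2"].to_numpy(float)) / 2.0
    elif {"time", "x", "y"}.issubset(cols):
        valid = df[["x", "y"]].notna().all(axis=1)
        df = df.loc[valid]
        x = df["x"].to_numpy(float)
        y = df["y"].to_numpy(float)
    else:
        raise DataValidationError(
            "position CSV must have columns time,x,y or time,x1,y1,x2,y2"
        )
    t = df["time"].to_numpy(float)
    if t.size < 2:
        raise DataValidationError("position track has fewer than 2 valid rows")
    if np.any(np.diff(t) <= 0):
        raise DataValidationError("position timestamps must be strictly increasing")
    fs_nominal = 1.0 / float(np.median(np.diff(t)))
    return PositionTrack(times=t, x=x, y=y, fs_nominal=fs_nominal)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Serialize an event table to CSV or JSON (by file extension).

    The round trip ``read_events(write_events(x)) == x`` holds to 1e-9 s.
    """
    events = validate_event_table(events)
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "event_table",
            "events": events[EVENT_COLUMNS].to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        events[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_events`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        records = payload["events"]
        df = pd.DataFrame(records, columns=EVENT_COLUMNS) if records else empty_event_table()
    else:
        df = pd.read_csv(path)
        if df.empty:
            return empty_event_table()
    df["has_sharp_wave"] = df["has_sharp_wave"].astype(bool)
    for c in EVENT_COLUMNS:
        if c not in ("session_id", "electrode_id", "region", "has_sharp_wave"):
            df[c] = df[c].astype(float)
    return validate_event_table(df[EVENT_COLUMNS])


def write_json_result(obj: dict, path: str | Path, kind: str) -> None:
    """Write an analysis-result dict as versioned JSON."""
    payload = {"schema_version": SCHEMA_VERSION, "kind": kind}
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))


def read_json_result(path: str | Path, kind: str | None = None) -> dict:
    payload = json.loads(Path(path).read_text())
    if kind is not None and payload.get("kind") != kind:
        raise DataValidationError(
            f"expected result kind {kind!r}, found {payload.get('kind')!r}"
        )
    return payload


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
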