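"""Ping-level I/O and echogram assembly.

Recreational-grade echosounders store each acoustic transmission ("ping")
as an 8-bit sample vector over a fixed range window, together with a GPS
fix and a millisecond UTC timestamp.  This module reads and writes those
records in a plain CSV schema, converts the 8-bit counts to a relative dB
scale, and assembles homogeneous ping sets into a 2-D echogram with depth
and along-track axes.

The dB mapping is ``20*log10(count/255)`` with zero counts clamped to one,
i.e. *relative* dB with full scale at 0 dB.  The manufacturer's exact
linear-to-dB mapping is proprietary; any affine-in-log alternative differs
only by a constant offset and gain, neither of which affects the
relative-intensity analysis downstream.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from ._utils import haversine_m

__all__ = [
    "PingRecord",
    "Echogram",
    "SchemaError",
    "read_ping_csv",
    "write_ping_csv",
    "counts_to_db",
    "pings_to_echogram",
    "utc_to_local",
    "local_to_utc",
    "DEFAULT_META",
]

#: Acquisition metadata of the study systems: 200 kHz transducer with a
#: 12 degree 3-dB beam angle and a 0.2 ms pulse, pinging at ~10 Hz.
DEFAULT_META = {
    "frequency_khz": 200.0,
    "pulse_width_ms": 0.2,
    "beam_angle_deg": 12.0,
    "sound_speed_ms": 1500.0,
    "gain_setting": "shallow-water-mode",
    "ping_rate_hz": 10.0,
}

_CSV_FIXED_COLS = ["survey_id", "ping", "utc_ms", "lat", "lon",
                   "min_range_m", "max_range_m", "n_samples"]


class SchemaError(ValueError):
    """Raised when a ping CSV does not match the documented schema."""


@dataclass
class PingRecord:
    """One acoustic transmission: navigation, range window, 8-bit samples."""

    survey_id: str
    ping_index: int
    time_utc_ms: int
    latitude: float
    longitude: float
    min_range_m: float
    max_range_m: float
    samples: np.ndarray  # uint8-valued integers in [0, 255]

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D vector")
        if not np.issubdtype(self.samples.dtype, np.integer):
            if not np.all(self.samples == np.round(self.samples)):
                raise ValueError("samples must be integers")
            self.samples = self.samples.astype(np.int64)
        if self.samples.size and (self.samples.min() < 0 or self.samples.max() > 255):
            raise ValueError(
                f"ping {self.ping_index}: sample values outside [0, 255]")
        if not (0 <= self.min_range_m < self.max_range_m):
            raise ValueError(
                f"ping {self.ping_index}: need 0 <= min_range < max_range")
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError(f"ping {self.ping_index}: coordinates out of range")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class Echogram:
    """Pings x depth-bins matrix of relative intensity (dB) with axes.

    ``intensity[p, i]`` is the relative intensity of ping ``p`` at depth
    ``depth_axis[i]`` (metres below the transducer).  ``along_track[p]``
    is the cumulative great-circle distance (m) travelled up to ping ``p``.
    """

    intensity: np.ndarray
    depth_axis: np.ndarray
    along_track: np.ndarray
    meta: dict = field(default_factory=lambda: dict(DEFAULT_META))

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        self.along_track = np.asarray(self.along_track, dtype=float)
        if self.intensity.shape != (self.along_track.size, self.depth_axis.size):
            raise ValueError("intensity shape does not match axes")
        if self.depth_axis.size > 1 and not np.all(np.diff(self.depth_axis) > 0):
            raise ValueError("depth_axis must be strictly increasing")
        if self.along_track.size > 1 and np.any(np.diff(self.along_track) < 0):
            raise ValueError("along_track must be non-decreasing")

    @property
    def n_pings(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_bins(self) -> int:
        return self.intensity.shape[1]

    @property
    def cell_height_m(self) -> float:
        """Vertical bin size (m)."""
        return float(self.depth_axis[1] - self.depth_axis[0])

    @property
    def cell_width_m(self) -> float:
        """Median along-track spacing between successive pings (m)."""
        d = np.diff(self.along_track)
        return float(np.median(d)) if d.size else 0.0

    def copy(self) -> "Echogram":
        return Echogram(self.intensity.copy(), self.depth_axis.copy(),
                        self.along_track.copy(), dict(self.meta))


def counts_to_db(counts):
    """8-bit sample counts -> relative dB, full scale (255) = 0 dB.

    ``dB = 20*log10(max(count, 1)/255)``; zero counts are clamped to one
    so the output is bounded in [-48.13, 0].
    """
    counts = np.asarray(counts)
    if counts.size and (np.min(counts) < 0 or np.max(counts) > 255):
        raise ValueError("counts must lie in [0, 255]")
    clamped = np.maximum(np.asarray(counts, dtype=float), 1.0)
    return 20.0 * np.log10(clamped / 255.0)


def write_ping_csv(records, path):
    """Write ping records to the pipeline CSV schema (bit-exact round trip)."""
    records = list(records)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIXED_COLS + ["samples"])
        for r in records:
            w.writerow([
                r.survey_id, r.ping_index, r.time_utc_ms,
                repr(float(r.latitude)), repr(float(r.longitude)),
                repr(float(r.min_range_m)), repr(float(r.max_range_m)),
                r.n_samples,
                " ".join(str(int(s)) for s in r.samples),
            ])


def read_ping_csv(path):
    """Read ping records written by :func:`write_ping_csv`.

    Malformed rows raise :class:`SchemaError` naming the line number;
    an empty file with a valid header yields an empty list.
    """
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, no header")
        expected = _CSV_FIXED_COLS + ["samples"]
        if header != expected:
            missing = set(expected) - set(header)
            raise SchemaError(
                f"{path}: header mismatch (missing columns: {sorted(missing)})")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected):
                raise SchemaError(f"{path}:{lineno}: wrong field count")
            try:
                samples = np.array([int(t) for t in row[8].split()], dtype=np.int64)
                rec = PingRecord(
                    survey_id=row[0],
                    ping_index=int(row[1]),
                    time_utc_ms=int(row[2]),
                    latitude=float(row[3]),
                    longitude=float(row[4]),
                    min_range_m=float(row[5]),
                    max_range_m=float(row[6]),
                    samples=samples,
                )
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
            if rec.n_samples != int(row[7]):
                raise SchemaError(
                    f"{path}:{lineno}: n_samples={row[7]} but "
                    f"{rec.n_samples} samples present")
            records.append(rec)
    return records


def pings_to_echogram(records, meta=None):
    """Assemble homogeneous ping records into an :class:`Echogram`.

    All records must share the same range window and sample count — a
    range or gain change mid-transect alters the (unknown) source level
    and invalidates relative-intensity comparability, so heterogeneous
    windows are rejected.

    Depth of bin ``i`` is ``min_range + i*(max_range - min_range)/(n-1)``;
    the along-track axis accumulates haversine distances between fixes.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 pings to build an echogram")
    r0 = records[0]
    for r in records[1:]:
        if (r.min_range_m != r0.min_range_m or r.max_range_m != r0.max_range_m
                or r.n_samples != r0.n_samples):
            raise ValueError(
                "heterogeneous range windows: range/gain changes invalidate "
                "relative-intensity comparability")
    counts = np.stack([r.samples for r in records])
    intensity = counts_to_db(counts)
    n = r0.n_samples
    depth_axis = r0.min_range_m + np.arange(n) * (
        (r0.max_range_m - r0.min_range_m) / (n - 1))
    lats = np.array([r.latitude for r in records])
    lons = np.array([r.longitude for r in records])
    steps = haversine_m(lats[:-1], lons[:-1], lats[1:], lons[1:])
    along = np.concatenate([[0.0], np.cumsum(steps)])
    m = dict(DEFAULT_META)
    if meta:
        m.update(meta)
    return Echogram(intensity, depth_axis, along, m)


_NZST = _dt.timezone(_dt.timedelta(hours=12), name="NZST")


def utc_to_local(time_utc):
    """UTC -> New Zealand Standard Time (fixed +12:00, no daylight saving)."""
    if isinstance(time_utc, (int, float)):
        time_utc = _dt.datetime.fromtimestamp(time_utc / 1000.0,
                                              tz=_dt.timezone.utc)
    if time_utc.tzinfo is None:
        time_utc = time_utc.replace(tzinfo=_dt.timezone.utc)
    return time_utc.astimezone(_NZST)


def local_to_utc(time_local):
    """NZST -> UTC (inverse of :func:`utc_to_local`)."""
    if time_local.tzinfo is None:
        time_local = time_local.replace(tzinfo=_NZST)
    return time_local.astimezone(_dt.timezone.utc)
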