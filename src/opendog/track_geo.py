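"""Read, quality-control, project, and time-match raw GPS tracks.

The measurement chain starts from raw 1 Hz GPS fixes for two actors (a dog
and its handler) recorded during a single open-field run.  This module turns
those fixes into a :class:`DyadTrack`: both actors resampled onto a common
one-second grid, expressed in a shared local metric frame, with per-step
speeds and headings ready for feature extraction.

Coordinate conventions
----------------------
* Geographic coordinates are WGS-84 decimal degrees.
* The metric frame is a local equirectangular projection anchored at a
  per-run origin (by default the handler-track centroid): x is meters east,
  y is meters north.  Within a field-sized domain (< 10 km) the projected
  step lengths agree with great-circle (haversine) distances to well below
  0.1 %, which is validated by tests.
* Headings use the navigation convention: degrees clockwise from north,
  in [0, 360).  A heading is undefined (NaN) for a zero-length step.
"""

from __future__ import annotations

import csv as _csv
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

#: default maximum plausible instantaneous speeds used by quality control
DEFAULT_MAX_SPEED_DOG = 15.0     # m/s; generous for a galloping dog
DEFAULT_MAX_SPEED_HANDLER = 4.0  # m/s; brisk human walk/jog
DEFAULT_MAX_GAP_S = 5.0          # gaps up to this long are interpolated

MIN_OVERLAP_S = 30.0


class TrackError(ValueError):
    """Base class for track ingestion and processing errors."""


class TrackFormatError(TrackError):
    """File failed to parse under the named standard."""


class DegenerateTrackError(TrackError):
    """Track has too few usable fixes."""


class UnusableTrackError(TrackError):
    """Quality control removed more than half of the fixes."""


class ProjectionDomainError(TrackError):
    """Track extends too far from the projection origin."""


class InsufficientOverlapError(TrackError):
    """Dog and handler tracks share too little common time."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeoPoint:
    """One GPS fix: time (s since run start), latitude, longitude (degrees)."""

    t: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError("GeoPoint time must be finite")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass
class GeoTrack:
    """Ordered GPS fixes for one actor in one run.

    Times must be non-decreasing; duplicate timestamps are tolerated here so
    that :func:`qc_track` can collapse and report them.  After QC the times
    are strictly increasing.
    """

    actor: str  # "dog" or "handler"
    run_id: str
    points: list[GeoPoint]

    def __post_init__(self) -> None:
        ts = [p.t for p in self.points]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("GeoTrack times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def t(self) -> np.ndarray:
        return np.array([p.t for p in self.points])

    @property
    def latlon(self) -> np.ndarray:
        return np.array([[p.lat, p.lon] for p in self.points])


@dataclass
class MetricTrack:
    """A track in the local metric frame: columns t, x (east m), y (north m)."""

    run_id: str
    origin: GeoPoint
    t: np.ndarray
    xy: np.ndarray  # shape (n, 2)

    def __len__(self) -> int:
        return len(self.t)

    def step_lengths(self) -> np.ndarray:
        return np.hypot(*np.diff(self.xy, axis=0).T)

    def total_length(self) -> float:
        return float(self.step_lengths().sum())


@dataclass
class Steps:
    """Per-step kinematics on a uniform grid.

    ``t`` holds the start time of each step [t, t+dt); ``heading`` is NaN for
    zero-length steps.
    """

    t: np.ndarray
    length: np.ndarray
    speed: np.ndarray
    heading: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class DyadTrack:
    """Dog and handler on a shared 1 Hz grid in a shared metric frame."""

    run_id: str
    matched_t: np.ndarray
    dog: MetricTrack
    handler: MetricTrack
    dog_steps: Steps
    handler_steps: Steps

    def __post_init__(self) -> None:
        n = len(self.matched_t)
        if len(self.dog) != n or len(self.handler) != n:
            raise ValueError("dog and handler must be sampled on matched_t")


@dataclass
class QCReport:
    """Accounting of what quality control did to a track."""

    n_input: int
    n_kept: int
    n_removed_speed: int = 0
    n_removed_duplicate: int = 0
    n_gap_filled: int = 0
    max_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.n_input != self.n_kept + self.n_removed_speed + self.n_removed_duplicate:
            raise ValueError("QCReport does not account for every input fix")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_GPX_NS = "http://www.topografix.com/GPX/1/1"


def _parse_iso8601(s: str) -> datetime:
    s = s.strip()
    if s.endswith("Z"):
        s = s[:-1] + "+00:00"
    dt = datetime.fromisoformat(s)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt


def read_track(path: str | Path, format: str | None = None,
               actor: str = "dog", run_id: str | None = None) -> GeoTrack:
    """Read a GPX 1.1 or CSV (``timestamp,lat,lon``) track file.

    Timestamps are sorted and rebased so the first fix is at t = 0.
    Raises :class:`TrackFormatError` for unparseable input and
    :class:`DegenerateTrackError` when fewer than 2 fixes are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gpx" if path.suffix.lower() == ".gpx" else "csv"
    if format == "gpx":
        rows = _read_gpx_rows(path)
    elif format == "csv":
        rows = _read_csv_rows(path)
    else:
        raise ValueError(f"unknown track format: {format!r}")

    if len(rows) < 2:
        raise DegenerateTrackError(f"{path}: {len(rows)} fixes (< 2)")
    rows.sort(key=lambda r: r[0])
    t0 = rows[0][0]
    pts = [GeoPoint(t=ts - t0, lat=lat, lon=lon) for ts, lat, lon in rows]
    if len({p.t for p in pts}) < 2:
        raise DegenerateTrackError(f"{path}: < 2 distinct timestamps")
    return GeoTrack(actor=actor, run_id=run_id or path.stem, points=pts)


def _read_gpx_rows(path: Path) -> list[tuple[float, float, float]]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise TrackFormatError(f"{path}: not valid XML ({e})") from e
    root = tree.getroot()
    ns = {"g": _GPX_NS}
    trkpts = root.findall(".//g:trk/g:trkseg/g:trkpt", ns)
    if not trkpts:  # tolerate un-namespaced GPX
        trkpts = root.findall(".//trk/trkseg/trkpt")
    rows = []
    for pt in trkpts:
        time_el = pt.find("g:time", ns)
        if time_el is None:
            time_el = pt.find("time")
        if time_el is None or time_el.text is None:
            raise TrackFormatError(f"{path}: trkpt without <time>")
        try:
            ts = _parse_iso8601(time_el.text).timestamp()
            lat = float(pt.attrib["lat"])
            lon = float(pt.attrib["lon"])
        except (KeyError, ValueError) as e:
            raise TrackFormatError(f"{path}: bad trkpt ({e})") from e
        rows.append((ts, lat, lon))
    return rows


def _read_csv_rows(path: Path) -> list[tuple[float, float, float]]:
    rows = []
    with open(path, newline="") as fh:
        reader = _csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or not row[0].strip():
                continue
            if i == 0 and row[0].strip().lower() in {"timestamp", "time", "t"}:
                continue
            if len(row) < 3:
                raise TrackFormatError(f"{path}:{i + 1}: expected timestamp,lat,lon")
            try:
                ts = _parse_iso8601(row[0]).timestamp()
                lat, lon = float(row[1]), float(row[2])
            except ValueError as e:
                raise TrackFormatError(f"{path}:{i + 1}: {e}") from e
            rows.append((ts, lat, lon))
    return rows


def write_track_csv(track: GeoTrack, path: str | Path,
                    start: datetime | None = None) -> None:
    """Write a GeoTrack as the ``timestamp,lat,lon`` CSV dialect."""
    start = start or datetime(2020, 1, 1, tzinfo=timezone.utc)
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["timestamp", "lat", "lon"])
        for p in track.points:
            ts = datetime.fromtimestamp(start.timestamp() + p.t, tz=timezone.utc)
            w.writerow([ts.isoformat().replace("+00:00", "Z"),
                        f"{p.lat:.8f}", f"{p.lon:.8f}"])


def write_track_gpx(track: GeoTrack, path: str | Path,
                    start: datetime | None = None) -> None:
    """Write a GeoTrack as a minimal GPX 1.1 file (trk/trkseg/trkpt/time)."""
    start = start or datetime(2020, 1, 1, tzinfo=timezone.utc)
    gpx = ET.Element("gpx", {
        "version": "1.1", "creator": "opendog", "xmlns": _GPX_NS,
    })
    trk = ET.SubElement(gpx, "trk")
    name = ET.SubElement(trk, "name")
    name.text = f"{track.run_id}:{track.actor}"
    seg = ET.SubElement(trk, "trkseg")
    for p in track.points:
        pt = ET.SubElement(seg, "trkpt",
                           {"lat": f"{p.lat:.8f}", "lon": f"{p.lon:.8f}"})
        tm = ET.SubElement(pt, "time")
        ts = datetime.fromtimestamp(start.timestamp() + p.t, tz=timezone.utc)
        tm.text = ts.isoformat().replace("+00:00", "Z")
    ET.indent(ET.ElementTree(gpx))
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def haversine_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in meters on a sphere of radius 6,371 km."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def to_metric(track: GeoTrack, origin: GeoPoint) -> MetricTrack:
    """Project to the local equirectangular frame anchored at ``origin``.

    x = R * dlon * cos(lat_origin), y = R * dlat (angles in radians).  Both
    actors of a dyad must share one origin so their frames coincide.
    Raises :class:`ProjectionDomainError` beyond 10 km from the origin.
    """
    latlon = track.latlon
    phi0 = math.radians(origin.lat)
    x = EARTH_RADIUS_M * np.radians(latlon[:, 1] - origin.lon) * math.cos(phi0)
    y = EARTH_RADIUS_M * np.radians(latlon[:, 0] - origin.lat)
    xy = np.column_stack([x, y])
    if np.hypot(x, y).max() > 10_000.0:
        raise ProjectionDomainError(
            f"track {track.run_id} extends > 10 km from projection origin")
    return MetricTrack(run_id=track.run_id, origin=origin, t=track.t, xy=xy)


def from_metric(xy: np.ndarray, origin: GeoPoint) -> np.ndarray:
    """Inverse of :func:`to_metric`: (x, y) meters -> (lat, lon) degrees."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    phi0 = math.radians(origin.lat)
    lat = origin.lat + np.degrees(xy[:, 1] / EARTH_RADIUS_M)
    lon = origin.lon + np.degrees(xy[:, 0] / (EARTH_RADIUS_M * math.cos(phi0)))
    return np.column_stack([lat, lon])


def track_centroid(track: GeoTrack) -> GeoPoint:
    """Mean lat/lon of a track, used as the default dyad projection origin."""
    latlon = track.latlon
    return GeoPoint(t=0.0, lat=float(latlon[:, 0].mean()),
                    lon=float(latlon[:, 1].mean()))


def heading_deg(dx: float | np.ndarray, dy: float | np.ndarray) -> np.ndarray:
    """Navigation heading of displacement (east, north): 0=N, 90=E, in [0,360)."""
    return np.mod(np.degrees(np.arctan2(dx, dy)), 360.0)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_track(track: GeoTrack, max_speed: float = DEFAULT_MAX_SPEED_DOG,
             max_gap: float = DEFAULT_MAX_GAP_S) -> tuple[GeoTrack, QCReport]:
    """Remove teleport artifacts, collapse duplicate timestamps, fill gaps.

    Fixes implying instantaneous speed above ``max_speed`` are removed
    iteratively (the later fix of the offending pair each pass).  Gaps up to
    ``max_gap`` seconds are filled by linear interpolation onto the 1 Hz
    grid; longer gaps are left as breaks.  Raises
    :class:`UnusableTrackError` if more than half of the fixes are removed.
    """
    if max_speed <= 0:
        raise ValueError("max_speed must be positive")
    pts = list(track.points)
    n_input = len(pts)

    # duplicate timestamps: keep first occurrence
    seen: set[float] = set()
    dedup: list[GeoPoint] = []
    n_dup = 0
    for p in pts:
        if p.t in seen:
            n_dup += 1
        else:
            seen.add(p.t)
            dedup.append(p)
    pts = dedup

    # iterative speed filter
    n_speed = 0
    changed = True
    while changed and len(pts) >= 2:
        changed = False
        kept = [pts[0]]
        for p in pts[1:]:
            dt = p.t - kept[-1].t
            v = haversine_distance(kept[-1], p) / dt if dt > 0 else math.inf
            if v > max_speed:
                n_speed += 1
                changed = True
            else:
                kept.append(p)
        pts = kept

    if n_speed + n_dup > n_input / 2 or len(pts) < 2:
        raise UnusableTrackError(
            f"{track.run_id}/{track.actor}: QC removed "
            f"{n_speed + n_dup}/{n_input} fixes")

    # gap filling on the 1 Hz grid
    filled: list[GeoPoint] = [pts[0]]
    n_fill = 0
    max_gap_seen = 0.0
    for prev, nxt in zip(pts, pts[1:]):
        gap = nxt.t - prev.t
        max_gap_seen = max(max_gap_seen, gap)
        if 1.0 < gap <= max_gap:
            # integer grid times strictly between the two fixes
            t_new = np.arange(math.floor(prev.t) + 1.0, nxt.t, 1.0)
            t_new = t_new[t_new > prev.t]
            for tn in t_new:
                w = (tn - prev.t) / gap
                filled.append(GeoPoint(
                    t=float(tn),
                    lat=prev.lat + w * (nxt.lat - prev.lat),
                    lon=prev.lon + w * (nxt.lon - prev.lon)))
                n_fill += 1
        filled.append(nxt)

    out = GeoTrack(actor=track.actor, run_id=track.run_id, points=filled)
    report = QCReport(n_input=n_input, n_kept=len(pts),
                      n_removed_speed=n_speed, n_removed_duplicate=n_dup,
                      n_gap_filled=n_fill, max_gap=max_gap_seen)
    return out, report


# ---------------------------------------------------------------------------
# time matching
# ---------------------------------------------------------------------------

def _interp_latlon(track: GeoTrack, grid: np.ndarray) -> np.ndarray:
    t = track.t
    latlon = track.latlon
    lat = np.interp(grid, t, latlon[:, 0])
    lon = np.interp(grid, t, latlon[:, 1])
    return np.column_stack([lat, lon])


def compute_steps(metric: MetricTrack) -> Steps:
    """Per-step length, speed, and navigation heading from consecutive fixes."""
    d = np.diff(metric.xy, axis=0)
    dt = np.diff(metric.t)
    length = np.hypot(d[:, 0], d[:, 1])
    speed = length / dt
    heading = heading_deg(d[:, 0], d[:, 1])
    heading = np.where(length > 0, heading, np.nan)
    return Steps(t=metric.t[:-1], length=length, speed=speed, heading=heading)


def time_match(dog: GeoTrack, handler: GeoTrack,
               origin: GeoPoint | None = None) -> DyadTrack:
    """Resample both actors onto the 1 Hz grid of their overlapping span.

    Both tracks are linearly interpolated in geographic coordinates, then
    projected with a single shared origin (the handler-track centroid unless
    given).  Raises :class:`InsufficientOverlapError` below 30 s of overlap.
    """
    t_lo = max(dog.points[0].t, handler.points[0].t)
    t_hi = min(dog.points[-1].t, handler.points[-1].t)
    if t_hi - t_lo < MIN_OVERLAP_S:
        raise InsufficientOverlapError(
            f"run {dog.run_id}: overlap {t_hi - t_lo:.1f} s < {MIN_OVERLAP_S} s")
    grid = np.arange(math.ceil(t_lo), math.floor(t_hi) + 1.0, 1.0)

    if origin is None:
        origin = track_centroid(handler)

    def project(track: GeoTrack) -> MetricTrack:
        ll = _interp_latlon(track, grid)
        gt = GeoTrack(actor=track.actor, run_id=track.run_id, points=[
            GeoPoint(t=float(t), lat=float(la), lon=float(lo))
            for t, (la, lo) in zip(grid, ll)])
        return to_metric(gt, origin)

    dog_m = project(dog)
    handler_m = project(handler)
    return DyadTrack(run_id=dog.run_id, matched_t=grid,
                     dog=dog_m, handler=handler_m,
                     dog_steps=compute_steps(dog_m),
                     handler_steps=compute_steps(handler_m))


def export_dyad_csv(dyad: DyadTrack, path: str | Path) -> None:
    """Write a DyadTrack as long-format CSV: t, x, y, actor."""
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["t", "x", "y", "actor"])
        for actor, m in (("dog", dyad.dog), ("handler", dyad.handler)):
            for t, (x, y) in zip(m.t, m.xy):
                w.writerow([f"{t:.1f}", f"{x:.4f}", f"{y:.4f}", actor])
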