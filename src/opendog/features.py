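"""The 18 per-run socio-spatial variables of a dog's open-field run.

Each run yields one :class:`FeatureVector` describing the dog's movement and
its relation to the handler, in five families:

* speed — MS (mean), MXS (max), VS (sample variance), TD (total distance);
* handler distance — MHD (mean), MXHD (max), VHD (variance), PTA
  (proportion of seconds in which the dog-handler distance decreases);
* orientation — OC (orientation consistency, the mean resultant length of
  the turning-angle distribution), DAD (mean cosine of successive turning
  angles; +1 means persistent forward motion), MTA (mean absolute turn,
  degrees);
* relative orientation — ROC (resultant length of dog-minus-handler
  headings), RAD (mean cosine of the dog heading relative to the bearing
  from dog to handler; +1 means always moving straight at the handler);
* path geometry and effort — FractalD (divider-method fractal dimension),
  SI (sinuosity), PO (path overlap, a grid revisitation index), ST
  (stamina, late/early mean-speed ratio), QT (quartering, crossings of the
  handler's travel axis per 100 m of handler travel).

A feature that is undefined for a run (e.g. sinuosity of a closed loop)
is reported as NaN and listed in ``missing``; missingness is explicit,
never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .track_geo import DyadTrack, MetricTrack, Steps, heading_deg

#: canonical feature order used by every downstream table
FEATURE_NAMES: tuple[str, ...] = (
    "MS", "MXS", "VS", "TD",
    "MHD", "MXHD", "VHD", "PTA",
    "OC", "DAD", "MTA",
    "ROC", "RAD",
    "FractalD", "SI", "PO", "ST", "QT",
)


class FeatureError(ValueError):
    pass


class RunRejectedError(FeatureError):
    """More features missing than the pipeline tolerates."""


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable constants of the feature definitions.

    overlap_cell: grid cell side (m) for path overlap, and the minimum net
    displacement below which sinuosity is declared degenerate.
    divider_scales: ruler lengths (m) for the divider fractal dimension.
    stamina_fraction: width of the early/late windows as a fraction of run
    duration.  min_step_for_heading: steps shorter than this (m) contribute
    no heading, so GPS jitter does not dominate the circular statistics.
    quartering_deadband: lateral offsets smaller than this (m) are ignored
    when counting axis crossings.
    """

    overlap_cell: float = 5.0
    divider_scales: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
    stamina_fraction: float = 1.0 / 3.0
    min_step_for_heading: float = 0.2
    quartering_deadband: float = 1.0
    max_missing: int = 4

    def __post_init__(self) -> None:
        s = self.divider_scales
        if len(s) < 4 or any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("divider_scales must be >= 4 strictly increasing values")


@dataclass
class FeatureVector:
    run_id: str
    dog_id: str
    group_label: str
    values: dict[str, float]
    missing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.values) != set(FEATURE_NAMES):
            raise ValueError("FeatureVector must carry exactly the 18 features")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES])


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def circular_mean_stats(angles_deg: Sequence[float] | np.ndarray
                        ) -> tuple[float, float]:
    """Circular mean direction and mean resultant length R of angles (deg).

    R is the norm of the average unit vector, in [0, 1].  When R == 0 the
    mean direction is undefined and returned as NaN.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise FeatureError("circular_mean_stats requires >= 1 angle")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = float(np.hypot(c, s))
    if r < 1e-12:
        return math.nan, 0.0
    return float(np.degrees(np.arctan2(s, c)) % 360.0), r


def wrap_angle_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-180, 180]."""
    return -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)


# ---------------------------------------------------------------------------
# feature families
# ---------------------------------------------------------------------------

def speed_features(steps: Steps) -> tuple[float, float, float, float]:
    """(MS, MXS, VS, TD): mean / max / sample variance of speed, total length."""
    if len(steps) < 2:
        raise FeatureError("speed_features needs >= 2 steps")
    v = steps.speed
    return (float(v.mean()), float(v.max()), float(v.var(ddof=1)),
            float(steps.length.sum()))


def handler_distance_features(dyad: DyadTrack
                              ) -> tuple[float, float, float, float]:
    """(MHD, MXHD, VHD, PTA) from per-second dog-handler distances."""
    if len(dyad.matched_t) < 2:
        raise FeatureError("handler_distance_features needs >= 2 matched fixes")
    d = np.hypot(*(dyad.dog.xy - dyad.handler.xy).T)
    diffs = np.diff(d)
    pta = float((diffs < 0).sum() / len(diffs))
    return float(d.mean()), float(d.max()), float(d.var(ddof=1)), pta


def _moving_headings(steps: Steps, min_step: float) -> np.ndarray:
    mask = (steps.length >= min_step) & np.isfinite(steps.heading)
    return steps.heading[mask]


def orientation_features(steps: Steps, min_step: float = 0.2
                         ) -> tuple[float, float, float]:
    """(OC, DAD, MTA) from headings of steps at least ``min_step`` long.

    Turns are wrapped successive heading differences in (-180, 180].  OC is
    the mean resultant length of the turning angles: 1 for perfectly
    consistent orientation step to step, 0 for uniformly scattered turns.
    DAD = mean cos(turn) is the first cosine moment of the same turn
    distribution (so OC and DAD are tightly coupled by construction, as
    observed for field dogs); MTA = mean |turn| in degrees.
    """
    h = _moving_headings(steps, min_step)
    if len(h) < 3:
        raise FeatureError("orientation_features needs >= 3 moving steps")
    turns = wrap_angle_deg(np.diff(h))
    _, oc = circular_mean_stats(turns)
    dad = float(np.cos(np.radians(turns)).mean())
    mta = float(np.abs(turns).mean())
    return oc, dad, mta


def relative_orientation_features(dyad: DyadTrack, min_step: float = 0.2
                                  ) -> tuple[float, float]:
    """(ROC, RAD).

    ROC is the mean resultant length of (dog heading - handler heading) over
    matched seconds where both actors moved.  RAD is the mean cosine of
    (dog heading - bearing from dog to handler) over seconds where the dog
    moved and the two actors were not coincident; +1 means the dog always
    moves directly toward the handler.
    """
    ds, hs = dyad.dog_steps, dyad.handler_steps
    dog_ok = (ds.length >= min_step) & np.isfinite(ds.heading)
    han_ok = (hs.length >= min_step) & np.isfinite(hs.heading)
    both = dog_ok & han_ok
    if both.sum() >= 3:
        _, roc = circular_mean_stats(ds.heading[both] - hs.heading[both])
    else:  # e.g. handler stationary all run
        roc = math.nan

    sep = dyad.handler.xy[:-1] - dyad.dog.xy[:-1]
    dist = np.hypot(sep[:, 0], sep[:, 1])
    rad_mask = dog_ok & (dist > 0)
    if rad_mask.sum() == 0:
        return roc, math.nan
    bearing = heading_deg(sep[rad_mask, 0], sep[rad_mask, 1])
    rad = float(np.cos(np.radians(ds.heading[rad_mask] - bearing)).mean())
    return roc, rad


# -- fractal dimension (divider / ruler method) -----------------------------

def divider_count(xy: np.ndarray, ruler: float) -> float:
    """Number of ruler strides needed to walk the polyline, with fractional
    remainder.

    Starting from the first vertex, each stride advances to the first point
    along the path (interpolated within segments) at chord distance ``ruler``
    from the current divider position; the leftover end-piece contributes its
    straight-line distance divided by the ruler.
    """
    xy = np.asarray(xy, dtype=float)
    if ruler <= 0:
        raise ValueError("ruler must be positive")
    p = xy[0]
    seg = 0            # current segment index
    a = xy[0]          # current position on that segment
    count = 0.0
    n = len(xy)
    while True:
        hit = None
        j, start = seg, a
        while j < n - 1:
            b = xy[j + 1]
            d = b - start
            f = start - p
            A = float(d @ d)
            if A > 0.0:
                B = 2.0 * float(f @ d)
                C = float(f @ f) - ruler * ruler
                disc = B * B - 4.0 * A * C
                if disc >= 0.0:
                    sq = math.sqrt(disc)
                    for t in ((-B - sq) / (2.0 * A), (-B + sq) / (2.0 * A)):
                        # tolerance at the segment end: a crossing landing
                        # exactly on a vertex must not be lost to rounding
                        if 1e-12 < t <= 1.0 + 1e-9:
                            hit = (j, start + min(t, 1.0) * d)
                            break
            if hit is not None:
                break
            j += 1
            start = xy[j]
        if hit is None:
            count += float(np.linalg.norm(xy[-1] - p)) / ruler
            return count
        count += 1.0
        seg, a = hit[0], hit[1]
        p = hit[1]


def fractal_dimension(track: MetricTrack,
                      scales: Sequence[float] = (2, 4, 8, 16, 32, 64),
                      ) -> float:
    """Divider-method fractal dimension of the path, clipped to [1, 2].

    Counts ruler strides N(s) at each scale s and returns minus the slope of
    the least-squares fit of log N(s) on log s.  The walk is performed from
    both ends and the counts averaged, which removes the slight direction
    dependence of a single divider pass.  Requires the path to be at least
    4x the largest ruler; raises for a degenerate (zero-length) path.
    """
    xy = track.xy
    total = track.total_length()
    if total <= 0:
        raise FeatureError("fractal_dimension: degenerate path")
    if total <= max(scales) * 4:
        raise FeatureError(
            f"fractal_dimension: path {total:.0f} m too short for scales")
    logs = np.log(np.asarray(scales, dtype=float))
    counts = np.array([(divider_count(xy, s) + divider_count(xy[::-1], s))
                       / 2.0 for s in scales])
    if np.any(counts <= 0):
        raise FeatureError("fractal_dimension: zero stride count")
    slope = np.polyfit(logs, np.log(counts), 1)[0]
    d = -float(slope)
    if not 1.0 <= d <= 2.0:
        import warnings
        warnings.warn(f"fractal dimension {d:.3f} outside [1, 2]; clipping")
        d = min(2.0, max(1.0, d))
    return d


def sinuosity(track: MetricTrack, min_net: float = 5.0) -> float:
    """Path length over net displacement (>= 1); NaN when the run returns
    within ``min_net`` meters of its start (out-and-back degenerate)."""
    net = float(np.linalg.norm(track.xy[-1] - track.xy[0]))
    if net <= min_net:
        return math.nan
    return track.total_length() / net


def path_overlap(track: MetricTrack, cell: float = 5.0) -> float:
    """Revisitation index on a square grid of side ``cell``.

    Fixes are discretized to cells, consecutive same-cell fixes collapse to a
    single entry, and PO = 1 - unique cells / cell entries, in [0, 1).
    """
    if len(track) < 2:
        raise FeatureError("path_overlap needs >= 2 fixes")
    cells = np.floor(track.xy / cell).astype(np.int64)
    keep = np.ones(len(cells), dtype=bool)
    keep[1:] = np.any(cells[1:] != cells[:-1], axis=1)
    entries = cells[keep]
    n_unique = len(np.unique(entries, axis=0))
    return 1.0 - n_unique / len(entries)


def stamina(steps: Steps, fraction: float = 1.0 / 3.0) -> float:
    """Late/early mean-speed ratio; < 1 indicates slowing over the run."""
    t = steps.t
    duration = t[-1] - t[0]
    if fraction * 3.0 > 1.0 + 1e-9 or len(steps) < 6 or duration <= 0:
        raise FeatureError("stamina: run too short for the window fraction")
    w = fraction * duration
    early = steps.speed[t <= t[0] + w]
    late = steps.speed[t >= t[-1] - w]
    if early.mean() == 0:
        return math.nan
    return float(late.mean() / early.mean())


def quartering(dyad: DyadTrack, deadband: float = 1.0) -> float:
    """Axis crossings of the dog across the handler's line of travel,
    per 100 m of handler travel.

    The signed lateral offset of the dog from the line through the handler's
    position along the handler's heading is computed each matched second;
    sign changes are counted after discarding offsets inside the dead-band.
    NaN when the handler never moves.
    """
    hs = dyad.handler_steps
    handler_td = float(hs.length.sum())
    if handler_td <= 0:
        return math.nan
    # forward-fill handler heading over stationary seconds
    heading = hs.heading.copy()
    valid = np.isfinite(heading)
    if not valid.any():
        return math.nan
    idx = np.maximum.accumulate(np.where(valid, np.arange(len(heading)), -1))
    usable = idx >= 0
    heading = heading[idx[usable]]
    rel = (dyad.dog.xy[:-1][usable] - dyad.handler.xy[:-1][usable])
    rad = np.radians(heading)
    u = np.column_stack([np.sin(rad), np.cos(rad)])  # unit heading, east/north
    # signed perpendicular offset: positive to the handler's right
    offset = u[:, 1] * rel[:, 0] - u[:, 0] * rel[:, 1]
    signs = np.sign(offset[np.abs(offset) >= deadband])
    crossings = int((signs[1:] != signs[:-1]).sum()) if len(signs) > 1 else 0
    return crossings / (handler_td / 100.0)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_features(dyad: DyadTrack, config: FeatureConfig | None = None,
                     dog_id: str = "", group_label: str = "") -> FeatureVector:
    """Compute all 18 features for one run; deterministic given inputs.

    Features whose preconditions fail are set to NaN and recorded in
    ``missing``.  Raises :class:`RunRejectedError` when more than
    ``config.max_missing`` features are missing.
    """
    cfg = config or FeatureConfig()
    vals: dict[str, float] = {}
    missing: list[str] = []

    def put(names: Sequence[str], fn) -> None:
        try:
            out = fn()
        except FeatureError:
            out = tuple(math.nan for _ in names)
        if not isinstance(out, tuple):
            out = (out,)
        for k, v in zip(names, out):
            vals[k] = v
            if isinstance(v, float) and math.isnan(v):
                missing.append(k)

    put(("MS", "MXS", "VS", "TD"), lambda: speed_features(dyad.dog_steps))
    put(("MHD", "MXHD", "VHD", "PTA"),
        lambda: handler_distance_features(dyad))
    put(("OC", "DAD", "MTA"),
        lambda: orientation_features(dyad.dog_steps, cfg.min_step_for_heading))
    put(("ROC", "RAD"),
        lambda: relative_orientation_features(dyad, cfg.min_step_for_heading))
    put(("FractalD",),
        lambda: fractal_dimension(dyad.dog, cfg.divider_scales))
    put(("SI",), lambda: sinuosity(dyad.dog, cfg.overlap_cell))
    put(("PO",), lambda: path_overlap(dyad.dog, cfg.overlap_cell))
    put(("ST",), lambda: stamina(dyad.dog_steps, cfg.stamina_fraction))
    put(("QT",), lambda: quartering(dyad, cfg.quartering_deadband))

    if len(missing) > cfg.max_missing:
        raise RunRejectedError(
            f"run {dyad.run_id}: {len(missing)} features missing: {missing}")
    return FeatureVector(run_id=dyad.run_id, dog_id=dog_id,
                         group_label=group_label, values=vals,
                         missing=missing)
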