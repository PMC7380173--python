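"""Seeded synthetic dyadic GPS cohorts for testing the full pipeline.

The study design being emulated: a handler walks an approximately square
path at a steady pace around a large grass field while an off-leash dog
explores freely, both carrying 1 Hz GPS receivers; each dog runs three
times, with the handler's walking direction randomized per run.

Dogs are simulated as correlated random walks whose heading each second is
drawn from a von Mises distribution around a blend of the previous heading
(persistence) and the bearing to a moving target — the handler's position
offset laterally by a sinusoid (quartering).  Speed is a truncated Gaussian
with an exponential fatigue decay.  Independent Gaussian jitter models GPS
error.  Four default archetypes span the two behavioral axes the analysis
is meant to recover — energetic exploration (speed, range, tortuosity) and
handler focus (attraction, relative orientation):

* ``rover_social`` — fast, handler-attracted, pronounced quartering
  (strong exploratory drive combined with social engagement);
* ``heeler`` — slow, strongly handler-attracted, little fatigue
  (social focus alone);
* ``liner`` — fast with high heading persistence and moderate attraction
  (sustained linear motion, moderate social focus);
* ``independent`` — fast, near-zero attraction, fatigues hardest
  (independent exploration, little human orientation).

Parameter values are declared fixtures chosen to look like plausible field
dogs, not estimates fitted to any real animal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .track_geo import (
    DyadTrack, GeoPoint, GeoTrack, from_metric, qc_track, time_match,
    DEFAULT_MAX_SPEED_DOG, DEFAULT_MAX_SPEED_HANDLER,
)

#: default field-site anchor (a rural Ohio field)
DEFAULT_ORIGIN_LAT = 41.41006
DEFAULT_ORIGIN_LON = -83.77353


@dataclass(frozen=True)
class HandlerSpec:
    """Square-walking handler: side (m), pace (m/s), run duration (s)."""

    side: float = 150.0
    speed: float = 1.4
    direction: str | None = None    # "cw", "ccw", or None = random per run
    origin_lat: float = DEFAULT_ORIGIN_LAT
    origin_lon: float = DEFAULT_ORIGIN_LON
    duration: float = 600.0
    heading_jitter_sd: float = 3.0  # degrees; makes the square "approximate"

    def __post_init__(self) -> None:
        if self.side <= 0 or self.speed <= 0 or self.duration <= 0:
            raise ValueError("side, speed and duration must be positive")


@dataclass(frozen=True)
class ArchetypeParams:
    """Generative parameters for one simulated behavioral type."""

    name: str
    base_speed_mean: float          # m/s
    base_speed_sd: float
    fatigue_rate: float             # per-s multiplicative speed decay
    persistence_kappa: float        # von Mises concentration of headings
    attraction_weight: float        # [0, 1] pull toward the handler target
    quartering_amp: float = 0.0     # m lateral sweep of the pursuit target
    quartering_period: float = 60.0  # s
    gps_noise_sd: float = 1.5       # m

    def __post_init__(self) -> None:
        if not 0.0 <= self.attraction_weight <= 1.0:
            raise ValueError("attraction_weight must be in [0, 1]")
        if self.persistence_kappa < 0 or self.base_speed_mean < 0:
            raise ValueError("kappa and speeds must be non-negative")


#: the four default archetypes (one per expected behavioral cluster).
#: Calibration notes: a heeling dog needs a speed surplus over the handler
#: (1.4 m/s) or it cannot close distance, and its tight orbit around the
#: moving handler is what makes the slow social dog tortuous; a fast social
#: dog is given only moderate attraction so it ranges in excursion-return
#: loops instead of orbiting (a perpetual orbit at high speed would inflate
#: its fractal dimension above every other type).
DEFAULT_ARCHETYPES: tuple[ArchetypeParams, ...] = (
    ArchetypeParams("rover_social", base_speed_mean=2.9, base_speed_sd=0.5,
                    fatigue_rate=2.5e-4, persistence_kappa=9.0,
                    attraction_weight=0.22, quartering_amp=12.0,
                    quartering_period=80.0),
    ArchetypeParams("heeler", base_speed_mean=2.1, base_speed_sd=0.4,
                    fatigue_rate=1e-4, persistence_kappa=6.0,
                    attraction_weight=0.85, quartering_amp=10.0,
                    quartering_period=18.0),
    ArchetypeParams("liner", base_speed_mean=2.5, base_speed_sd=0.35,
                    fatigue_rate=1.5e-4, persistence_kappa=18.0,
                    attraction_weight=0.06, quartering_amp=4.0,
                    quartering_period=80.0),
    ArchetypeParams("independent", base_speed_mean=3.3, base_speed_sd=0.6,
                    fatigue_rate=5e-4, persistence_kappa=8.0,
                    attraction_weight=0.05, quartering_amp=0.0,
                    quartering_period=60.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """A simulated study: archetypes x dogs x repeated runs."""

    archetypes: tuple[tuple[ArchetypeParams, int], ...] = tuple(
        (a, 4) for a in DEFAULT_ARCHETYPES)
    runs_per_dog: int = 3
    master_seed: int = 0
    handler: HandlerSpec = HandlerSpec()
    dog_jitter_sd: float = 0.05   # per-dog individuality (relative)
    run_state_sd: float = 0.10    # per-run arousal: speed up, attraction down

    def __post_init__(self) -> None:
        if self.runs_per_dog < 1 or any(n < 1 for _, n in self.archetypes):
            raise ValueError("need >= 1 dog per archetype and >= 1 run per dog")


@dataclass
class CohortRun:
    """One simulated dyad plus its provenance."""

    dog_id: str
    archetype: str
    run_index: int
    seed: int
    dog_track: GeoTrack
    handler_track: GeoTrack
    dyad: DyadTrack


# ---------------------------------------------------------------------------
# handler
# ---------------------------------------------------------------------------

def handler_square_path(spec: HandlerSpec, seed: int | np.random.SeedSequence,
                        run_id: str = "run") -> GeoTrack:
    """1 Hz track of a handler pacing the square perimeter.

    The walk starts at a random corner and heads for successive corners with
    Gaussian heading jitter; a clockwise walk is the exact y-mirror of the
    counter-clockwise walk generated from the same seed.
    """
    rng = np.random.default_rng(seed)
    direction = spec.direction or ("cw" if rng.random() < 0.5 else "ccw")
    half = spec.side / 2.0
    corners = np.array([[half, half], [-half, half],
                        [-half, -half], [half, -half]])  # ccw order
    ci = int(rng.integers(4))
    pos = corners[ci].astype(float)
    target = (ci + 1) % 4
    n = int(spec.duration) + 1
    xy = np.empty((n, 2))
    xy[0] = pos
    for i in range(1, n):
        to = corners[target] - pos
        dist = float(np.hypot(*to))
        if dist < spec.speed:  # arrived: aim at the next corner
            target = (target + 1) % 4
            to = corners[target] - pos
            dist = float(np.hypot(*to))
        bearing = math.atan2(to[0], to[1])
        h = bearing + math.radians(rng.normal(0.0, spec.heading_jitter_sd))
        pos = pos + spec.speed * np.array([math.sin(h), math.cos(h)])
        xy[i] = pos
    if direction == "cw":
        xy = xy * np.array([1.0, -1.0])
    origin = GeoPoint(t=0.0, lat=spec.origin_lat, lon=spec.origin_lon)
    latlon = from_metric(xy, origin)
    points = [GeoPoint(t=float(i), lat=float(la), lon=float(lo))
              for i, (la, lo) in enumerate(latlon)]
    return GeoTrack(actor="handler", run_id=run_id, points=points)


# ---------------------------------------------------------------------------
# dog
# ---------------------------------------------------------------------------

def _handler_xy_heading(handler: GeoTrack, origin: GeoPoint
                        ) -> tuple[np.ndarray, np.ndarray]:
    from .track_geo import to_metric
    m = to_metric(handler, origin)
    d = np.diff(m.xy, axis=0)
    head = np.arctan2(d[:, 0], d[:, 1])
    head = np.append(head, head[-1])
    # forward-fill headings through stationary seconds
    lengths = np.append(np.hypot(d[:, 0], d[:, 1]), 1.0)
    for i in range(1, len(head)):
        if lengths[i - 1] == 0:
            head[i] = head[i - 1]
    return m.xy, head


def simulate_dog(arch: ArchetypeParams, handler: GeoTrack,
                 seed: int | np.random.SeedSequence,
                 run_id: str = "run") -> GeoTrack:
    """Correlated-random-walk dog responding to the handler track.

    Each second the dog's heading is a von Mises draw around the circular
    blend of its previous heading (weight ``1 - attraction_weight``) and the
    bearing to the quartering target riding on the handler; its speed is a
    non-negative Gaussian draw damped by exponential fatigue.  GPS noise is
    added to the emitted fixes only, not to the underlying dynamics.
    """
    rng = np.random.default_rng(seed)
    origin = GeoPoint(t=0.0, lat=handler.points[0].lat,
                      lon=handler.points[0].lon)
    hxy, hhead = _handler_xy_heading(handler, origin)
    n = len(hxy)
    pos = hxy[0].copy()
    heading = float(rng.uniform(0.0, 2.0 * math.pi))
    w = arch.attraction_weight
    xy = np.empty((n, 2))
    xy[0] = pos
    for i in range(1, n):
        t = float(i)
        # quartering target: handler position offset perpendicular to its travel
        lateral = arch.quartering_amp * math.sin(
            2.0 * math.pi * t / arch.quartering_period)
        hh = hhead[min(i, n - 1)]
        perp = np.array([math.cos(hh), -math.sin(hh)])  # right of travel
        target = hxy[min(i, n - 1)] + lateral * perp
        to = target - pos
        if np.hypot(*to) > 1e-9:
            bearing = math.atan2(to[0], to[1])
        else:
            bearing = heading
        # circular blend of persistence and attraction
        vx = (1.0 - w) * math.sin(heading) + w * math.sin(bearing)
        vy = (1.0 - w) * math.cos(heading) + w * math.cos(bearing)
        mu = math.atan2(vx, vy) if (vx, vy) != (0.0, 0.0) else heading
        if arch.persistence_kappa > 0:
            heading = float(rng.vonmises(mu, arch.persistence_kappa))
        else:
            heading = float(rng.uniform(-math.pi, math.pi))
        speed = max(0.0, rng.normal(arch.base_speed_mean, arch.base_speed_sd))
        speed *= math.exp(-arch.fatigue_rate * t)
        pos = pos + speed * np.array([math.sin(heading), math.cos(heading)])
        xy[i] = pos
    if arch.gps_noise_sd > 0:
        xy = xy + rng.normal(0.0, arch.gps_noise_sd, size=xy.shape)
    latlon = from_metric(xy, origin)
    points = [GeoPoint(t=float(i), lat=float(la), lon=float(lo))
              for i, (la, lo) in enumerate(latlon)]
    return GeoTrack(actor="dog", run_id=run_id, points=points)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(spec: CohortSpec | None = None) -> list[CohortRun]:
    """Simulate every dog x run dyad of a cohort, QC'd and time-matched.

    Seeds derive deterministically from ``master_seed`` and the (dog, run)
    indices, so the same spec reproduces the same cohort bit for bit.
    """
    spec = spec or CohortSpec()
    runs: list[CohortRun] = []
    dog_index = 0
    for arch, n_dogs in spec.archetypes:
        for d in range(n_dogs):
            dog_id = f"{arch.name}_{d + 1:02d}"
            # per-dog individuality: one latent quality factor shifts speed
            # and handler attraction together (well-bred field dogs tend to
            # be both energetic and handler-bound), plus independent jitter
            drng = np.random.default_rng(
                np.random.SeedSequence((spec.master_seed, dog_index, 9999)))
            js = spec.dog_jitter_sd
            q = drng.normal()
            dog_arch = replace(
                arch,
                base_speed_mean=arch.base_speed_mean * max(
                    0.1, 1.0 + js * q + drng.normal(0.0, js / 2)),
                attraction_weight=float(np.clip(
                    arch.attraction_weight * (1.0 + 1.0 * js * q
                                              + drng.normal(0.0, js / 2)),
                    0.01, 1.0)))
            for r in range(spec.runs_per_dog):
                run_id = f"{dog_id}_r{r + 1}"
                ss = np.random.SeedSequence((spec.master_seed, dog_index, r))
                h_seed, d_seed, s_seed = ss.spawn(3)
                # arousal state of the day: an excited run is faster but
                # checks in with the handler less
                e = float(np.random.default_rng(s_seed).normal())
                rs = spec.run_state_sd
                run_arch = replace(
                    dog_arch,
                    base_speed_mean=dog_arch.base_speed_mean * max(
                        0.1, 1.0 + rs * e),
                    attraction_weight=float(np.clip(
                        dog_arch.attraction_weight * (1.0 - 2.0 * rs * e),
                        0.01, 1.0)))
                handler = handler_square_path(spec.handler, h_seed, run_id)
                dog = simulate_dog(run_arch, handler, d_seed, run_id)
                dog_qc, _ = qc_track(dog, DEFAULT_MAX_SPEED_DOG)
                han_qc, _ = qc_track(handler, DEFAULT_MAX_SPEED_HANDLER)
                dyad = time_match(dog_qc, han_qc)
                runs.append(CohortRun(
                    dog_id=dog_id, archetype=arch.name, run_index=r + 1,
                    seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                    dog_track=dog, handler_track=handler, dyad=dyad))
            dog_index += 1
    return runs
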