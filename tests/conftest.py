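"""Shared fixtures: tiny constructed tracks and one simulated cohort.

Everything is generated programmatically; the cohort fixture is session-
scoped because the full simulate -> extract -> analyze chain is the most
expensive thing the suite does.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import opendog as od
from opendog import pipeline as P
from opendog.track_geo import (
    DyadTrack, GeoPoint, GeoTrack, MetricTrack, Steps, compute_steps,
)

FIELD_LAT, FIELD_LON = 41.41006, -83.77353


def make_metric_track(xy, run_id="t", t=None) -> MetricTrack:
    xy = np.asarray(xy, dtype=float)
    if t is None:
        t = np.arange(len(xy), dtype=float)
    origin = GeoPoint(t=0.0, lat=FIELD_LAT, lon=FIELD_LON)
    return MetricTrack(run_id=run_id, origin=origin, t=np.asarray(t, float),
                       xy=xy)


def make_dyad(dog_xy, handler_xy, run_id="t") -> DyadTrack:
    dog = make_metric_track(dog_xy, run_id)
    handler = make_metric_track(handler_xy, run_id)
    return DyadTrack(run_id=run_id, matched_t=dog.t, dog=dog,
                     handler=handler, dog_steps=compute_steps(dog),
                     handler_steps=compute_steps(handler))


def make_geotrack(xy, actor="dog", run_id="t", t=None) -> GeoTrack:
    """Build a GeoTrack whose metric projection equals ``xy`` (meters)."""
    from opendog.track_geo import from_metric
    xy = np.asarray(xy, dtype=float)
    if t is None:
        t = np.arange(len(xy), dtype=float)
    origin = GeoPoint(t=0.0, lat=FIELD_LAT, lon=FIELD_LON)
    latlon = from_metric(xy, origin)
    return GeoTrack(actor=actor, run_id=run_id, points=[
        GeoPoint(t=float(ti), lat=float(la), lon=float(lo))
        for ti, (la, lo) in zip(t, latlon)])


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 4 archetypes x 4 dogs x 3 runs."""
    return od.simulate_cohort(od.CohortSpec(master_seed=0))


@pytest.fixture(scope="session")
def cohort_feature_table(default_cohort) -> pd.DataFrame:
    dyads = [(r.dyad, r.dog_id, r.archetype) for r in default_cohort]
    return P.extract_feature_table(dyads, od.FeatureConfig())


@pytest.fixture(scope="session")
def cohort_analysis(cohort_feature_table):
    """Full statistics stack on the default cohort (n_boot reduced: the
    estimation stage is exercised separately at full size)."""
    opts = P.AnalysisOptions(n_boot=2000)
    return P.analyze_feature_table(cohort_feature_table, opts, seed=0)


@pytest.fixture
def single_dyad(default_cohort) -> DyadTrack:
    return default_cohort[0].dyad
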