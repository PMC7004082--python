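"""Shared fixtures: hand-built tracks and small generating models."""

import numpy as np
import pandas as pd
import pytest

from sitefidelity.geo import enu_to_latlon
from sitefidelity.hmm import MovementHMM
from sitefidelity.tracks import Trip

COLONY = (78.90, 12.10)


def fixes_from_enu(offsets_m, t0="2017-06-15 06:00", interval_min=10.0,
                   colony=COLONY):
    """Build a fix table from (east, north) metre offsets around the colony."""
    xy = np.asarray(offsets_m, dtype=float)
    lat, lon = enu_to_latlon(colony[0], colony[1], xy[:, 0], xy[:, 1])
    t = pd.Timestamp(t0) + pd.to_timedelta(np.arange(len(xy)) * interval_min,
                                           unit="m")
    return pd.DataFrame({"t": t, "lat": lat, "lon": lon})


def make_trip(offsets_m, complete=True, **kw):
    return Trip(trip_id="T1", bird_id="b1", fixes=fixes_from_enu(offsets_m, **kw),
                complete=complete, stage="incubation", colony_id="A")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_hmm():
    """A well-conditioned 3-state model used by oracle comparisons."""
    return MovementHMM(
        step_mean=[500.0, 100.0, 30.0], step_sd=[300.0, 80.0, 25.0],
        angle_mean=[0.0, np.pi, 0.5], angle_kappa=[5.0, 1.5, 0.3],
        tpm=[[0.8, 0.1, 0.1], [0.2, 0.7, 0.1], [0.3, 0.3, 0.4]],
        delta=[0.5, 0.3, 0.2])


def sample_obs(model, T, rng):
    """Draw one (steps, angles) sequence from an HMM; first angle missing."""
    S = model.n_states
    states = np.zeros(T, dtype=int)
    states[0] = rng.choice(S, p=model.delta)
    for t in range(1, T):
        states[t] = rng.choice(S, p=model.tpm[states[t - 1]])
    m, s = model.step_mean[states], model.step_sd[states]
    steps = rng.gamma(m * m / (s * s), s * s / m)
    angles = rng.vonmises(model.angle_mean[states],
                          np.maximum(model.angle_kappa[states], 1e-8))
    angles[0] = np.nan
    return steps, angles, states
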