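"""Shared fixtures: constructed recordings and session-scoped synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import graphokin as gk
from graphokin.trace_model import Recording, WriterMeta


def make_recording(t=None, x=None, y=None, pressure=None, tilt_x=None,
                   tilt_y=None, on_surface=None, rate=200.0, n=None,
                   label="unknown", writer_id="w0") -> Recording:
    """Build a valid recording, defaulting every unspecified channel."""
    if t is None:
        assert n is not None
        t = np.arange(n) / rate
    t = np.asarray(t, dtype=float)
    n = len(t)

    def default(v, fill):
        if v is None:
            return np.full(n, fill, dtype=float)
        v = np.asarray(v, dtype=float)
        return v

    return Recording(
        t=t,
        x=default(x, 0.0),
        y=default(y, 0.0),
        pressure=default(pressure, 0.5),
        tilt_x=default(tilt_x, 10.0),
        tilt_y=default(tilt_y, -20.0),
        on_surface=(np.ones(n, dtype=bool) if on_surface is None
                    else np.asarray(on_surface, dtype=bool)),
        sampling_rate=rate,
        meta=WriterMeta(id=writer_id, label=label),
    )


@pytest.fixture(scope="session")
def td_profile():
    return gk.default_profiles()["td"]


@pytest.fixture(scope="session")
def d_profile():
    return gk.default_profiles()["d"]


@pytest.fixture(scope="session")
def short_td_trace(td_profile):
    """One 60-s typically-developing trace for feature-level tests."""
    return gk.generate_trace(td_profile.replace(duration=60.0), seed=101)


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort (16 TD + 8 D, 60-s traces) with features."""
    profiles = gk.default_profiles()
    spec = gk.CohortSpec(
        n_td=16, n_d=8,
        td_profile=profiles["td"].replace(duration=60.0),
        d_profile=profiles["d"].replace(duration=60.0),
        seed=202,
    )
    recordings, truth = gk.generate_cohort(spec)
    cohort = gk.extract_cohort(recordings)
    return recordings, cohort, truth
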