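"""Shared fixtures: reduced-scale synthetic sessions (generated once per run)."""

import numpy as np
import pytest

from hdemg.recording import ArrayGeometry, Recording
from hdemg.synth import make_fixture


@pytest.fixture(scope="session")
def separable_session():
    session, _ = make_fixture("separable", 0)
    return session


@pytest.fixture(scope="session")
def spatial_session():
    session, _ = make_fixture("spatial_only", 0)
    return session


@pytest.fixture(scope="session")
def fatigue_session():
    session, _ = make_fixture("fatigue_drift", 0)
    return session


@pytest.fixture(scope="session")
def gel_session():
    session, _ = make_fixture("gel_drift", 0)
    return session


def tiny_recording(
    torque,
    fs=512.0,
    task="flexion",
    target_level=0.10,
    phase="submaximal",
    n_channels_noise=0.01,
    rec_id="tiny",
    seed=0,
):
    """A minimal 2x2 single-muscle recording wrapping a given torque trace."""
    torque = np.asarray(torque, dtype=float)
    geom = ArrayGeometry("T", 2, 2, muscle_regions=(("biceps_brachii", (1, 2)),))
    rng = np.random.default_rng(seed)
    signals = rng.normal(0, n_channels_noise, (4, torque.size))
    return Recording(
        signals=signals,
        fs=fs,
        geometries=(geom,),
        torque=torque,
        task=task,
        target_level=target_level,
        phase=phase,
        rec_id=rec_id,
    )
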