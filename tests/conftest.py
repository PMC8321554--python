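"""Shared fixtures: small synthetic movies and default parameter sets."""

from __future__ import annotations

import numpy as np
import pytest

from patchdyn.core import DetectionParams, Movie, TrackingParams
from patchdyn.synth import SyntheticSpec, simulate_movie


@pytest.fixture
def detection_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def tracking_params() -> TrackingParams:
    return TrackingParams()


@pytest.fixture
def flat_movie() -> Movie:
    """A 20-frame constant movie (no dynamics)."""
    return Movie(np.full((20, 32, 32), 50.0), pixel_size_um=0.13, frame_interval_s=4.0)


@pytest.fixture(scope="session")
def default_simulation():
    """One seeded default-condition simulation shared across read-only tests."""
    return simulate_movie(SyntheticSpec(rng_seed=42))


@pytest.fixture
def tiny_spec() -> SyntheticSpec:
    """Single small bouton, short movie — cheap to simulate."""
    return SyntheticSpec(
        n_boutons=1,
        bouton_radius_um=1.5,
        margin_um=0.6,
        n_frames=30,
        rng_seed=0,
    )
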