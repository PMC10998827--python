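"""Shared fixtures: phantom geometry, grids, and simulated volumes.

Everything is generated programmatically; expensive objects are session-scoped
so the suite builds each phantom/volume once.
"""

from __future__ import annotations

import numpy as np
import pytest

import sirtiq
from sirtiq import (SpectVolume, assign_activity, build_geometry, default_grid,
                    get_setup, rasterize)

try:  # derandomize hypothesis when present
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def geometry():
    return build_geometry("standard")


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def labels(geometry, grid):
    return rasterize(geometry, grid)


@pytest.fixture(scope="session")
def tc_8to1(labels):
    """Tc-99m 8:1 filling: (setup record, activity volume)."""
    rec = get_setup("tc99m", "8to1")
    return rec, assign_activity(labels, rec.setup)


@pytest.fixture(scope="session")
def ho_8to1(labels):
    rec = get_setup("ho166", "8to1")
    return rec, assign_activity(labels, rec.setup)


@pytest.fixture(scope="session")
def ideal_volume(ho_8to1):
    """Noise- and blur-free volume: the activity map itself."""
    _, activity = ho_8to1
    return SpectVolume.from_activity(activity)


@pytest.fixture(scope="session")
def tc_volume(tc_8to1):
    """One default Tc-99m SPECT surrogate (20 s x 120 projections)."""
    rec, activity = tc_8to1
    cam = sirtiq.default_camera("tc99m")
    iso = sirtiq.ISOTOPES["tc99m"]
    return sirtiq.simulate_spect(activity, cam, iso, 20.0, 120, seed=11)
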