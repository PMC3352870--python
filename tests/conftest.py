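"""Shared fixtures: small, fast phantom specs for unit tests.

Unit tests run on a reduced scan grid (25 B-scans x 128 A-scans x 160
depth px) with proportionally scaled anatomy so each phantom renders and
segments in well under a second; geometry-sensitive acceptance checks use
the full default grid in test_acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pytest

from onhquant.phantom import PhantomSpec, make_phantom


def small_spec(**overrides) -> PhantomSpec:
    base = dict(
        n_bscans=25,
        n_ascans=128,
        n_depth=160,
        bscan_spacing=150.0,  # keep the 15 deg x 15 deg field with fewer B-scans
        retina_thickness_px=50.0,
        rpe_center_row=100.0,
        rpe_curvature=5e-4,
        disc_radius_px=18.0,
        swell_amplitude_px=25.0,
        swell_sigma_px=14.0,
        rnfl_band_px=4.0,
        rpe_band_px=4.0,
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


ZERO_NOISE = {"speckle_shape": None, "additive_sigma": 0.0}


@pytest.fixture(scope="session")
def clean_phantom():
    """Zero-noise small phantom with a swelling and a disc gap."""
    return make_phantom(small_spec(**ZERO_NOISE))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise small phantom."""
    return make_phantom(small_spec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
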