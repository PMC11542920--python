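"""Shared fixtures: small rendered scenes with known ground truth."""
from __future__ import annotations

import numpy as np
import pytest

from aquaflux import synth
from aquaflux.core import ImageStack


@pytest.fixture(scope="session")
def osmotic_challenge_trace():
    """Hypertonic 300→400 mOsM challenge at t=60 s, back at t=120 s."""
    params = synth.OsmoticParams()
    proto = synth.ChallengeProtocol(
        c_out=(300.0, 400.0, 300.0),
        breakpoints=(0.0, 60.0, 120.0),
        duration=300.0,
    )
    return synth.simulate_osmotic_volume(params, proto, dt=0.2)


@pytest.fixture(scope="session")
def noiseless_fit_scene(osmotic_challenge_trace):
    """One cell, no noise, no bleach: analytic intensity everywhere."""
    imaging = synth.ImagingParams(
        F0_scale=1000.0, background_offset=100.0, noise_sd=0.0, pixel_size_um=2.0
    )
    stack, truth = synth.render_fit_stack(
        [osmotic_challenge_trace], [(32.0, 32.0)], imaging, field_shape_rc=(64, 64)
    )
    return stack, truth, imaging


@pytest.fixture()
def uniform_stack():
    return ImageStack(
        data=np.full((20, 32, 32), 7.0), pixel_size_um=2.0, frame_interval_s=1.0
    )
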