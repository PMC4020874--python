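"""Shared fixtures: small, fast phantoms for the unit suite.

The small phantom keeps the full 140-frame time axis (so the spectral
machinery sees its design conditions) but shrinks the image plane so that
3-D median filtering and per-frame edge detection stay cheap.
"""

import numpy as np
import pytest

from corneadyn import PhantomParams, generate_phantom


def small_params(**overrides) -> PhantomParams:
    """Phantom parameters scaled to a 120×192×140 frame block."""
    defaults = dict(
        dims=(120, 192, 140),
        apex_row=25.0,
        sagitta_px=20.0,
        band_thickness_px=18.0,
        deflection_amplitude_px=20.0,
        deflection_sigma_px=30.0,
        deflection_margin_cols=40,
        eyeball_right_px=0.0,
        iris_bands=((85.0, 95.0, 0.95),),
        noise_sigma=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noiseless small phantom: indentation + eyeball tilt, no ripple."""
    return generate_phantom(small_params(eyeball_right_px=8.0, seed=11))


@pytest.fixture(scope="session")
def ripple_phantom():
    """Small phantom with a 300 Hz, 2 px oscillation over frames 50-89."""
    return generate_phantom(
        small_params(
            deflection_amplitude_px=15.0,
            ripple_freq_hz=300.0,
            ripple_amp_px=2.0,
            ripple_start_frame=50,
            ripple_stop_frame=90,
            seed=12,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
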