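"""Shared fixtures: reference media and small synthetic acquisitions."""

import numpy as np
import pytest

import swelast as sw
from swelast.simulate import wavefield_to_displacement


@pytest.fixture(scope="session")
def liver_twe_medium():
    """Kelvin-Voigt liver parameters from the torsional-wave fit."""
    return sw.Medium(sw.KelvinVoigtParams(mu=1512.0, eta=0.536))


@pytest.fixture(scope="session")
def liver_swei_medium():
    """Kelvin-Voigt liver parameters from the imaging-branch fit."""
    return sw.Medium(sw.KelvinVoigtParams(mu=1019.0, eta=0.628))


@pytest.fixture(scope="session")
def hydrogel_medium():
    """Soft low-viscosity hydrogel-phantom parameters."""
    return sw.Medium(sw.KelvinVoigtParams(mu=615.0, eta=0.093))


@pytest.fixture(scope="session")
def lateral_grid():
    return np.arange(0.0, 12.001e-3, 0.3e-3)


@pytest.fixture(scope="session")
def slow_time_grid():
    # 20 ms at PRI 100 us -> 50 Hz DFT bins, tones land exactly on bins
    return np.arange(0.0, 0.02, 100e-6)


@pytest.fixture(scope="session")
def kv_wavefield(liver_swei_medium, lateral_grid, slow_time_grid):
    """Noiseless dispersive wavefield with band-limited tone-comb source."""
    return sw.simulate_wavefield(liver_swei_medium, lateral_grid,
                                 slow_time_grid, sw.tone_comb())


@pytest.fixture(scope="session")
def tracked_iq(hydrogel_medium, slow_time_grid):
    """Hydrogel wavefield tracked by the IQ simulator at 40 dB SNR."""
    x = np.arange(0.0, 7.2e-3, 0.3e-3)  # 24 lateral positions
    field = sw.simulate_wavefield(hydrogel_medium, x, slow_time_grid,
                                  sw.tone_comb())
    disp = wavefield_to_displacement(field)
    depth = np.linspace(14e-3, 18e-3, 32)
    d3 = np.broadcast_to(disp[None], (depth.size,) + disp.shape)
    iq = sw.simulate_iq(d3, depth, x=x, snr_db=40.0, seed=7)
    return field, disp, iq
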