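import numpy as np
import pytest
from hypothesis import settings

import cellmech as cm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def probe():
    return cm.ProbeParams()


@pytest.fixture(scope="session")
def noiseless_curve(probe):
    """Half-space Hertz curve: E = 10 kPa, no baseline, no noise."""
    return cm.simulate_force_curve(10e3, np.inf, probe, baseline_slope_pn_per_nm=0.0,
                                   noise_sd_pn=0.0, seed=0)


@pytest.fixture(scope="session")
def small_cell():
    """16x16 virtual cell, 10 kPa body / 16 kPa periphery, 0-5 um heights."""
    return cm.make_virtual_cell(
        shape=(16, 16), cell_radius_um=12.0, max_height_um=5.0,
        e_cell_pa=10e3, e_periphery_factor=1.6, pixel_size_um=1.875, seed=0,
    )


@pytest.fixture(scope="session")
def processed_small_map(small_cell):
    """Noisy simulated force volume of the small cell plus pipeline output."""
    fv, truth = cm.simulate_force_volume(small_cell, noise_sd_pn=10.0, seed=3)
    result = cm.process_force_volume(fv)
    return fv, truth, result
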