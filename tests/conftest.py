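import numpy as np
import pytest

from cinedense import mechanics as mech
from cinedense import phantom as ph


@pytest.fixture(scope="session")
def small_spec():
    """A quick-to-render mouse-like phantom used across the suite."""
    return ph.PhantomSpec(
        grid=(64, 64), R_endo_mm=4.0, R_epi_mm=6.0, n_frames=12, seed=7
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return ph.render_slice(small_spec)


@pytest.fixture(scope="session")
def small_phantom_noisefree(small_spec):
    from dataclasses import replace

    return ph.render_slice(replace(small_spec, phase_noise_sd_rad=0.0))


@pytest.fixture(scope="session")
def small_full_result(small_phantom):
    dense, gt = small_phantom
    return mech.analyze_slice(dense, gt.contour_set)
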