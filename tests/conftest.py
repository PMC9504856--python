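import numpy as np
import pytest

import aquaspec as aq
from aquaspec.core import linear_offset_correct, average_group
from aquaspec.synthetic import NOISE_FREE, bulk_water_profile

DESIGN = (0.0, 0.01, 0.03, 0.05, 0.07, 0.10)


@pytest.fixture(scope="session")
def library():
    return aq.load_profile_library()


@pytest.fixture(scope="session")
def grid():
    """Full-resolution instrument grid (10,000-4000 cm^-1 at 2 cm^-1)."""
    return aq.WavenumberGrid.default()


@pytest.fixture(scope="session")
def coarse_grid():
    """Cheap grid for tests that do not rely on 2 cm^-1 resolution."""
    return aq.WavenumberGrid.default(step=8.0)


@pytest.fixture(scope="session")
def pp_averaged(library, grid):
    """Noise-free averaged PP concentration series on the full grid."""
    ds = aq.synthesize_dataset([library["PP"]], DESIGN, n_prep=1, n_meas=1,
                               noise=NOISE_FREE, seed=0, grid=grid)
    return average_group(linear_offset_correct(ds))


@pytest.fixture(scope="session")
def water_reference(grid):
    """Offset-corrected bulk-water spectrum at 10 % equivalent amplitude."""
    return linear_offset_correct(
        aq.synthesize_sample(bulk_water_profile(), 0.10, grid=grid))
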