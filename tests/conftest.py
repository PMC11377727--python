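import warnings

import numpy as np
import pytest

import wstomo as w

# The shifted Ewald caps legitimately truncate at the axial band edge on the
# compact test grids; that contract is tested explicitly in test_kspace.
warnings.filterwarnings(
    "ignore", message="Ewald cap truncated", category=UserWarning
)


@pytest.fixture(scope="session")
def grid16():
    return w.FrequencyGrid((16, 16, 16), (0.4, 0.4, 0.4))


@pytest.fixture(scope="session")
def bead_vol_16():
    return w.bead_phantom(
        (16, 16, 16), (0.4, 0.4, 0.4), [((0.0, 0.0, 0.0), 2.0, 1.36)], n_m=1.33
    )


def _bead_frame(z_D: float) -> w.IntensityFrame:
    """One simulated sensor frame of a 5 μm bead at the given defocus."""
    vol = w.bead_phantom(
        (512, 512, 32), (0.835, 0.835, 1.0), [((0.0, 0.0, 0.0), 5.0, 1.594)],
        n_m=1.58,
    )
    cfg = w.ScanConfig(
        wavelengths=(0.43,), n_m=1.58, z_D=z_D, sensor_pitch=1.67,
        upsample=2, nz=32, dz=1.0, guard=32, passes=1,
    )
    frames, _ = w.simulate_scan(vol, cfg)
    return frames[0]


@pytest.fixture(scope="session")
def bead_frame_400():
    return _bead_frame(400.0)


@pytest.fixture(scope="session")
def bead_frame_414():
    return _bead_frame(414.0)


@pytest.fixture(scope="session")
def bead_frame_630():
    return _bead_frame(630.0)
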