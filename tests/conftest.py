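import numpy as np
import pytest

from colonyflow import CalibrationProfile, SimulationSpec, simulate_sequence


@pytest.fixture
def calib():
    """0.5 μm/px at 8-min intervals: 1 px/frame = 3.75 μm/h."""
    return CalibrationProfile(microns_per_pixel=0.5, minutes_per_frame=8.0)


@pytest.fixture(scope="session")
def small_capture():
    """Small synthetic capture (128², 5 frames, 30 μm/h) with truth."""
    spec = SimulationSpec(
        height=128,
        width=128,
        n_frames=5,
        speed_um_per_h=30.0,
        calibration=CalibrationProfile(0.5, 8.0),
        seed=1,
    )
    return simulate_sequence(spec)


@pytest.fixture(scope="session")
def textured_image():
    """Static textured field for flow tests (periodic, so shifts are exact)."""
    from colonyflow.synthetic import _bandpass_noise

    rng = np.random.default_rng(2)
    return 0.5 + 0.15 * _bandpass_noise(rng, (160, 160), 6.0)
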