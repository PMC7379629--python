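import numpy as np
import pytest

import smallfield as sf

#: coarse grid pitch (mm) used in tests to keep simulated maps small; the
#: profile model is smooth so sizing accuracy is limited by pitch, which the
#: assertions account for
TEST_PITCH_MM = 0.25


@pytest.fixture(scope="session")
def noiseless_campaign() -> sf.SyntheticCampaign:
    """Noise-free campaign on the default beam, both reference detectors."""
    cfg = sf.SimulationConfig(
        seed=11, pitch_mm=TEST_PITCH_MM,
        noise={"EBT3": 0.0, "W1": 0.0, "diode": 0.0})
    return sf.simulate_campaign(cfg, detectors=("EBT3", "W1"), map_noise=False)


@pytest.fixture(scope="session")
def noisy_campaign() -> sf.SyntheticCampaign:
    """Campaign with default percent-level noise and one solid-state detector."""
    cfg = sf.SimulationConfig(seed=23, pitch_mm=TEST_PITCH_MM)
    return sf.simulate_campaign(
        cfg, detectors=("EBT3", "W1", "PTW 60019 mD"))


@pytest.fixture()
def gaussian_map() -> sf.DoseMap2D:
    """Noiseless bivariate Gaussian dose map (a=2 Gy, b=3 mm, c=4 mm)."""
    pitch = 0.1
    n = 120
    coords = pitch * np.arange(-n, n + 1)
    xx, yy = np.meshgrid(coords, coords)
    vals = 2.0 * np.exp(-0.5 * ((xx / 3.0) ** 2 + (yy / 4.0) ** 2))
    return sf.DoseMap2D(values=vals, spacing_x=pitch, spacing_y=pitch)
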