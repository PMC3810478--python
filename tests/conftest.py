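import numpy as np
import pytest

from hdimtools.models import DetectionGrid, FluorophoreModel


@pytest.fixture(scope="session")
def paper_grid() -> DetectionGrid:
    """The 2 polarization x 16 spectral x 64 time-gate reference grid."""
    return DetectionGrid.paper_default()


@pytest.fixture(scope="session")
def small_grid() -> DetectionGrid:
    """A reduced 2 x 4 x 8 grid for fast tests."""
    return DetectionGrid(
        time_edges=tuple(np.linspace(0.0, 12.5, 9)),
        laser_period_T=12.5,
        wavelength_edges=tuple(np.linspace(440.0, 630.0, 5)),
        polarization_states=("parallel", "perpendicular"),
    )


@pytest.fixture(scope="session")
def fluor_a() -> FluorophoreModel:
    """Reference fluorophore A: tau 3 ns, r0 0.4, theta 12 ns, peak 495 nm."""
    return FluorophoreModel(
        lifetime_tau=3.0,
        limiting_anisotropy_r0=0.4,
        rot_corr_theta=12.0,
        spectral_peak=495.0,
        spectral_fwhm=50.0,
        name="A",
    )


@pytest.fixture(scope="session")
def fluor_b() -> FluorophoreModel:
    """Reference fluorophore B: tau 2 ns, r0 0.2, theta 1 ns, peak 505 nm."""
    return FluorophoreModel(
        lifetime_tau=2.0,
        limiting_anisotropy_r0=0.2,
        rot_corr_theta=1.0,
        spectral_peak=505.0,
        spectral_fwhm=50.0,
        name="B",
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231028)
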