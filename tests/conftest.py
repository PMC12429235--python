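import numpy as np
import pytest

from trachea_sr import (
    AnalysisConfig,
    Bifurcation,
    FbmPerturbation,
    TubeSpec,
    make_tube_mask,
    trachea_phantom,
)


@pytest.fixture(scope="session")
def smooth_bif():
    """Smooth circular trachea phantom with a distal bifurcation."""
    spec = trachea_phantom(amplitude_rms=0.0)
    mask, truth = make_tube_mask(spec)
    return mask, truth


@pytest.fixture(scope="session")
def textured_bif():
    """fBm-textured (1 mm RMS, H=0.5) bifurcating phantom."""
    spec = trachea_phantom(amplitude_rms=1.0, hurst=0.5, seed=11)
    mask, truth = make_tube_mask(spec)
    return mask, truth


@pytest.fixture(scope="session")
def straight_tube():
    """Straight circular tube, radius 9 mm, no bifurcation."""
    spec = TubeSpec(base_radius=9.0, length=60.0)
    mask, truth = make_tube_mask(spec)
    return mask, truth


@pytest.fixture(scope="session")
def elliptical_bif():
    """Constant d_c/d_s = 0.75 bifurcating phantom."""
    spec = TubeSpec(base_radius=9.0, length=110.0, cross_section_ratio=0.75,
                    bifurcation=Bifurcation(z_split_mm=30.0))
    mask, truth = make_tube_mask(spec)
    return mask, truth


@pytest.fixture(scope="session")
def bowed_bif():
    """Bowed centerline (5 mm amplitude), smooth circular cross-sections."""
    spec = TubeSpec(base_radius=9.0, length=110.0, bow_amplitude_mm=5.0,
                    bifurcation=Bifurcation(z_split_mm=30.0))
    mask, truth = make_tube_mask(spec)
    return mask, truth


@pytest.fixture(scope="session")
def fbm_straight():
    """fBm texture (1 mm RMS, H=0.5) on a straight tube, known carina=0."""
    spec = TubeSpec(base_radius=9.0, length=110.0,
                    perturbation=FbmPerturbation(hurst=0.5, amplitude_rms=1.0, seed=7),
                    bifurcation=Bifurcation(z_split_mm=30.0))
    mask, truth = make_tube_mask(spec)
    return mask, truth


@pytest.fixture()
def default_config():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
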