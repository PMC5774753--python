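import numpy as np
import pytest

from chronopewma.radiocarbon import synthesize_curve


@pytest.fixture(scope="session")
def identity_curve():
    """μ(θ) = θ with zero curve error: calibration collapses to a Gaussian."""
    return synthesize_curve((12000.0, 13000.0), step=5.0)


@pytest.fixture(scope="session")
def wiggle_curve():
    """Steep sinusoidal wiggles (amplitude·2π/period ≈ 1.6 > 1): the curve has
    reversals, so single radiocarbon ages map to several calendar ranges."""
    return synthesize_curve(
        (11800.0, 13200.0),
        base_offset=1850.0,
        wiggle_amplitude=130.0,
        wiggle_period=500.0,
        error_level=15.0,
        step=5.0,
    )


@pytest.fixture(scope="session")
def experiment_curve():
    """The default synthetic stand-in curve used by the experiment engine."""
    return synthesize_curve(
        (11800.0, 13200.0),
        base_offset=1850.0,
        wiggle_amplitude=55.0,
        wiggle_period=310.0,
        error_level=40.0,
        step=5.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
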