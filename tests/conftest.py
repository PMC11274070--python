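import pytest

from cleftsim import default_cleft, default_sim, default_wall, WallParams


@pytest.fixture(scope="session")
def cleft():
    """Physiological cleft parameters (d=20 nm, D=0.33 um^2/ms, V=-4 mV)."""
    return default_cleft()


@pytest.fixture(scope="session")
def wall():
    return default_wall()


@pytest.fixture(scope="session")
def wall_off():
    return WallParams(variant="off")


@pytest.fixture
def fast_sim():
    """Small, quick simulation protocol for unit tests."""
    return default_sim(n_runs=500, seed=123)
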