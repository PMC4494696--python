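import numpy as np
import pytest

from dgetag.synthetic import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def default_scenario():
    """One full default-condition study, shared across read-only tests."""
    return simulate_study(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def clean_scenario():
    """Reduced-depth study with zero error/antisense/novel rates."""
    cfg = SyntheticConfig(
        seed=5, error_rate=0.0, antisense_rate=0.0, novel_rate=0.0,
        library_depths={"X1": 200_000, "X2": 180_000, "Xin": 80_000},
        de_spec=[("X1", 15, 8.0), ("Xin", 10, 8.0)],
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
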