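import numpy as np
import pytest

from frorfot.fitting import FitConfig
from frorfot.model import FrOrParameters, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def light_fit_config():
    """Reduced multistart for batch tests where the heuristic start suffices."""
    return FitConfig(n_lattice_starts=2)


def random_params(rng: np.random.Generator, n: int = 1) -> list[FrOrParameters]:
    """In-bounds physiologic parameter draws for round-trip exercises."""
    out = []
    for _ in range(n):
        out.append(
            FrOrParameters(
                FrL=float(rng.uniform(0.02, 0.6)),
                alpha=float(rng.uniform(0.3, 0.95)),
                FrC=float(rng.uniform(0.01, 0.12)),
                beta=float(rng.uniform(0.3, 0.95)),
            )
        )
    return out
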