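import numpy as np
import pytest

from raschmiss import DEFAULT_BANK, SimulationConfig, simgen
from raschmiss.types import ResponseData


@pytest.fixture(scope="session")
def bank():
    return DEFAULT_BANK


@pytest.fixture(scope="session")
def study_pair():
    """One (complete, incomplete) replication under the study's default design."""
    cfg = SimulationConfig(seed=99, pi=0.3)
    complete, incomplete, latents, streams = simgen.simulate_incomplete(cfg, 0)
    return complete, incomplete


@pytest.fixture(scope="session")
def big_complete(bank):
    """Large complete dataset for consistency checks."""
    lat = simgen.draw_latents(100_000, rho=0.0, seed=4)
    return simgen.simulate_responses(lat, bank, seed=5)


@pytest.fixture()
def tiny_incomplete():
    """Hand-written 6 x 5 matrix exercising eligibility and margins."""
    nan = np.nan
    values = np.array(
        [
            [1, 0, 1, 1, 0],          # complete
            [1, nan, 1, 1, 0],        # 4 observed, eligible
            [1, 0, nan, nan, 1],      # 3 observed, eligible
            [1, nan, nan, nan, 0],    # 2 observed, ineligible
            [nan, nan, nan, nan, nan],  # nothing observed
            [0, 1, 0, nan, 1],        # 4 observed, eligible
        ],
        dtype=float,
    )
    return ResponseData(values)
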