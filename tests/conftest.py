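import numpy as np
import pandas as pd
import pytest

from mirhythm import SimulationConfig, simulate_expression
from mirhythm.io import validate_metadata

#: the emulated time-course design: 4 h sampling, unequal replication
TIMEPOINTS = (10.0, 14.0, 18.0, 22.0, 26.0, 30.0)
REPLICATES = (4, 4, 4, 4, 4, 5)


@pytest.fixture(scope="session")
def design_times() -> np.ndarray:
    return np.repeat(np.asarray(TIMEPOINTS), np.asarray(REPLICATES))


@pytest.fixture(scope="session")
def design_meta(design_times) -> pd.DataFrame:
    ids, reps = [], []
    for zt, n in zip(TIMEPOINTS, REPLICATES):
        ids.extend(f"ZT{zt:g}_r{i + 1}" for i in range(n))
        reps.extend(range(1, n + 1))
    return validate_metadata(
        pd.DataFrame({"sample_id": ids, "zt_hours": design_times, "replicate": reps})
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition simulated dataset shared by read-only tests."""
    return simulate_expression(SimulationConfig(n_families=60, seed=11))
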