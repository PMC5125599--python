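import numpy as np
import pytest

from metapopnet.synthetic_data import (
    PopulationSpec,
    SyntheticConfig,
    WithinMoveKernel,
)

#: In/Out counts of the four clustered populations (NE, C, NW, W) in the
#: published total network, used as a worked example throughout.
TABLE2_COUNTS = [[78, 34], [13, 12], [52, 8], [20, 14]]


def two_population_config(
    seed: int,
    flow_ab: float,
    flow_ba: float,
    pairs: float = 100.0,
    years=(1998, 2008),
) -> SyntheticConfig:
    """Minimal two-population scenario for flow-asymmetry power/calibration checks."""
    return SyntheticConfig(
        populations=(
            PopulationSpec("A", 47.0, 1.0, 20_000.0, pairs),
            PopulationSpec("B", 48.5, 5.0, 20_000.0, pairs),
        ),
        years=years,
        flow_matrix=((1 - flow_ab, flow_ab), (flow_ba, 1 - flow_ba)),
        seed=seed,
        ring_prob=0.8,
        resight_prob=0.8,
        within_move=WithinMoveKernel(),
        location_sigma_km=20.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def table2_counts():
    return [row[:] for row in TABLE2_COUNTS]
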