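import logging

import pytest

from fluxcore import ToyModelSpec, generate_toy_model

logging.getLogger("cobra").setLevel(logging.WARNING)

#: demand chosen strictly between the legacy quantization levels
#: (0 < 0.3 < 0.05 * 10), so the LP bound is strictly tighter than legacy's
BACKFLOW_DEMAND = 0.3


@pytest.fixture(scope="session")
def perfect_fixture():
    """Bow tie with no obligatory backflow: minimum inflow is exactly 0."""
    return generate_toy_model(
        ToyModelSpec(n_core_precursors=3, n_peripheral_branches=2, seed=7)
    )


@pytest.fixture(scope="session")
def backflow_fixture():
    """One peripheral route (PER_1 -> BACK_1) obligatorily feeds the core.

    seed=1 makes BR_2 reversible, adding a second (zeroable) boundary
    reaction; the analytic minimum inflow is 0.3 * mu = 0.3.
    """
    return generate_toy_model(
        ToyModelSpec(
            n_core_precursors=3,
            n_peripheral_branches=2,
            backflow_demands=(BACKFLOW_DEMAND,),
            reversible_fraction=0.5,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def random_specs():
    """Small randomized specs for oracle cross-checks (kept <= 16 reactions)."""
    specs = []
    for i in range(20):
        n_back = i % 3
        specs.append(
            ToyModelSpec(
                n_core_precursors=1 + i % 3,
                n_peripheral_branches=i % 3,
                backflow_demands=tuple(
                    0.05 + 0.37 * ((i * 7 + k * 3) % 10) / 10.0
                    for k in range(n_back)
                ),
                reversible_fraction=(i % 4) / 3.0,
                seed=100 + i,
            )
        )
    return specs
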