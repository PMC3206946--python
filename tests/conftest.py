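import numpy as np
import pytest
from hypothesis import settings

from photoquad import CommunityConfig, HierarchyConfig, IncidenceGrid

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_grid():
    """4 quadrats x 3 taxa, hand-checkable."""
    return IncidenceGrid(
        incidence=np.array([[1, 0, 1], [0, 0, 1], [1, 1, 0], [0, 0, 0]]),
        taxa=("alga", "sponge", "bryozoan"),
        row=np.array([0, 0, 1, 1]),
        col=np.array([0, 1, 1, 0]),
        side_cm=25.0,
        plot_id="toy",
        site="S1",
        region="R1",
    )


@pytest.fixture
def six_taxa_grid():
    """3 quadrats x 6 taxa for the taxon-rule truth table."""
    return IncidenceGrid(
        incidence=np.array(
            [
                [1, 0, 0, 0, 1, 1],
                [0, 1, 1, 1, 0, 0],
                [0, 0, 0, 0, 0, 1],
            ]
        ),
        taxa=("A", "B", "C", "D", "E", "F"),
        row=np.array([0, 0, 0]),
        col=np.array([0, 1, 2]),
        side_cm=20.0,
        plot_id="rules-toy",
    )


@pytest.fixture
def sim_grid():
    """Default simulated plot: 64 quadrats, patchy occupancy."""
    from photoquad import simulate_grid

    return simulate_grid(CommunityConfig(seed=11), plot_id="sim", site="S1", region="R1")


@pytest.fixture
def hierarchy_table():
    """Replicate table from the default 3-region x 3-site hierarchy fixture."""
    from photoquad import hierarchy_replicates

    return hierarchy_replicates(HierarchyConfig(base=CommunityConfig(seed=5)))
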