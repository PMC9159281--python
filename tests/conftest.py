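import numpy as np
import pytest

from multimerge.refl_model import SpaceGroupSetting, UnitCell
from multimerge.synthetic import SimulationConfig, choose_d_min, simulate

TETRA_CELL = UnitCell(79.1, 79.1, 38.0)


@pytest.fixture(scope="session")
def p41212_group():
    return SpaceGroupSetting.from_symbol("P 41 21 2")


@pytest.fixture(scope="session")
def tetra_cell():
    return TETRA_CELL


@pytest.fixture(scope="session")
def d_min_300_p4():
    """Resolution limit giving ~300 unique reflections for a P4 crystal."""
    return choose_d_min(TETRA_CELL, "P 4", 300)


@pytest.fixture(scope="session")
def ambiguous_p4_collection(d_min_300_p4):
    """20 small-wedge data sets with a planted twofold indexing ambiguity."""
    cfg = SimulationConfig(
        space_group="P 4",
        d_min=d_min_300_p4,
        ambiguity_op="k,h,-l",
        ambiguity_fraction=0.5,
        n_datasets=20,
        noise=10.0,
        sampling="random",
        multiplicity=20.0,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_p41212_collection():
    """Homogeneous tetragonal collection, moderate noise, unit scales."""
    cfg = SimulationConfig(
        space_group="P 41 21 2",
        d_min=3.2,
        n_datasets=12,
        noise=15.0,
        scale_range=(1.0, 1.0),
        b_range=(0.0, 0.0),
        sampling="random",
        multiplicity=8.0,
        seed=21,
    )
    return simulate(cfg)
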