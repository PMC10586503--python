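import numpy as np
import pandas as pd
import pytest

import supplyscape as ss


@pytest.fixture(scope="session")
def config():
    return ss.SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_panel(config):
    return ss.simulate_index_panel(config)


@pytest.fixture(scope="session")
def index_frame(sim_panel):
    frame, _ = ss.build_index_panel(sim_panel)
    return frame


@pytest.fixture(scope="session")
def lattice_weights(config):
    return ss.make_lattice_weights(config)


@pytest.fixture(scope="session")
def partition(config):
    return ss.make_partition(config)


@pytest.fixture(scope="session")
def fixture_set():
    return ss.fixtures()


@pytest.fixture()
def tiny_schema():
    """Two-indicator schema (one cost-type) for hand-checkable panels."""
    return ss.IndicatorSchema(
        indicators=(
            ss.IndicatorSpec(id="a", label="a", dimension="care_service", direction=1,
                             fixed_weight=0.6),
            ss.IndicatorSpec(id="b", label="b", dimension="health_support", direction=-1,
                             fixed_weight=0.4),
        )
    )


def tiny_panel_frame(values_a, values_b, units=("u1", "u2"), years=(2010, 2011)):
    rows = []
    i = 0
    for u in units:
        for y in years:
            rows.append(
                {"unit_id": u, "region_id": "north", "year": y,
                 "a": values_a[i], "b": values_b[i]}
            )
            i += 1
    return pd.DataFrame(rows)
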