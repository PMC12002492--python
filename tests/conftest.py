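import numpy as np
import pandas as pd
import pytest

from soilrisk.reference import ELEMENTS, SURVEY_STATS, pavlodar_registry
from soilrisk.sample_io import SampleTable
from soilrisk.synthetic_data import generate_field, preset


@pytest.fixture(scope="session")
def registry():
    return pavlodar_registry()


@pytest.fixture(scope="session")
def survey_stats():
    return SURVEY_STATS


@pytest.fixture(scope="session")
def elements():
    return ELEMENTS


@pytest.fixture(scope="session")
def paper_like_table(registry):
    table, truth = generate_field(preset("paper_like", seed=3))
    return table, truth


def make_table(conc: dict, coords: np.ndarray | None = None) -> SampleTable:
    """Build a SampleTable from an element->values dict with metric coords."""
    n = len(next(iter(conc.values())))
    if coords is None:
        rng = np.random.default_rng(12345)
        coords = rng.uniform(0, 10_000, (n, 2))
    frame = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], **{k: np.asarray(v, float) for k, v in conc.items()}},
        index=pd.Index([f"S{i:02d}" for i in range(n)], name="site_id"),
    )
    return SampleTable(frame=frame, elements=list(conc))
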