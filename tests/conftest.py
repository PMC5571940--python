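import numpy as np
import pytest
from shapely.geometry import box

from beetlekern.landscape import classify_edge_core
from beetlekern.synthetic import (
    StudyDesign,
    baseline_truth,
    simulate_study,
)

MASTER_SEED = 20150325


@pytest.fixture(scope="session")
def tiny_raster():
    """Two rectangular woods on a 100 m grid."""
    polys = [box(0, 0, 300, 200), box(1000, 1000, 1400, 1200)]
    return classify_edge_core(polys, band=100.0, resolution=100.0)


@pytest.fixture(scope="session")
def small_design():
    """A down-scaled study: 2 sites x 4 fields x 5 points x 4 dates."""
    return StudyDesign(
        n_sites=2,
        fields_per_site=4,
        site_extent=(2500.0, 2500.0),
        wood_cover=(0.18, 0.3),
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    return simulate_study(small_design, baseline_truth(), MASTER_SEED)


@pytest.fixture(scope="session")
def small_table(small_study):
    return small_study.table


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
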