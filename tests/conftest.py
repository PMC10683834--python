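import numpy as np
import pytest

from appki.analytic_models import mixed_rate_law
from appki.assay_protocols import RateTable

UM = 1e-6
NM = 1e-9


def make_mixed_table(Kic, Kiu, Vmax=1e-7, Km=10 * UM, s_grid=None, i_grid=None, case_id="closed_form"):
    """Noise-free rate table generated directly from the mixed rate law."""
    if s_grid is None:
        s_grid = np.geomspace(2 * UM, 50 * UM, 6)
    if i_grid is None:
        lo = min(k for k in (Kic, Kiu) if k is not None)
        hi = max(k for k in (Kic, Kiu) if k is not None)
        i_grid = np.concatenate([[0.0], np.geomspace(0.3 * lo, 3 * hi, 5)])
    records = [
        (float(s), np.nan, float(i), mixed_rate_law(Vmax, Km, Kic, Kiu, s, i))
        for s in s_grid
        for i in i_grid
    ]
    return RateTable(records, metadata={"case_id": case_id, "varied": "S"})


@pytest.fixture
def mixed_table_5_20():
    return make_mixed_table(5 * UM, 20 * UM)


@pytest.fixture
def competitive_table():
    return make_mixed_table(10 * NM, None, i_grid=np.concatenate([[0.0], np.geomspace(3 * NM, 100 * NM, 5)]))


@pytest.fixture
def uncompetitive_table():
    return make_mixed_table(None, 20 * UM, i_grid=np.concatenate([[0.0], np.geomspace(5 * UM, 60 * UM, 5)]))
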