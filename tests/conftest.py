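import numpy as np
import pandas as pd
import pytest

from growthmsm.anthropometry import synthetic_reference_table
from growthmsm.multistate import MSMParams


@pytest.fixture(scope="session")
def lms_table():
    return synthetic_reference_table().validate()


@pytest.fixture(scope="session")
def paper_scale_params():
    """Band intensities at the published per-1000-person-month scale."""
    q = np.array([
        [0.0372, 0.0116, 0.0068],   # healthy -> malnourished
        [0.0096, 0.0201, 0.0003],   # healthy -> death
        [0.15, 0.10, 0.05],         # malnourished -> healthy
        [0.0353, 0.0840, 0.0060],   # malnourished -> death
    ])
    return MSMParams(log_q0=np.log(q))


@pytest.fixture(scope="session")
def toy_panel():
    """Ten children on a mixed visit grid with panel states and one exact death."""
    rng = np.random.default_rng(42)
    rows = []
    for cid in range(10):
        times = np.sort(rng.choice(np.arange(1, 40), size=5, replace=False)).astype(float)
        state = 1
        for j, t in enumerate(times):
            if state != 3 and rng.random() < 0.25:
                state = 2 if state == 1 else 1
            rows.append({"child_id": cid, "age_months": t, "state": state,
                         "obs_type": "panel"})
        if cid == 7:
            rows.append({"child_id": cid, "age_months": times[-1] + 2.5,
                         "state": 3, "obs_type": "exact_death"})
    return pd.DataFrame(rows)
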