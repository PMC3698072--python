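import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import immunosig as im

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20130625)


def build_panel(values, sex, diagnosis, columns, ids=None):
    ids = ids or [f"S{i:02d}" for i in range(len(sex))]
    idx = pd.Index(ids, name="subject_id")
    vals = pd.DataFrame(np.asarray(values, dtype=float), index=idx,
                        columns=columns)
    meta = pd.DataFrame({"sex": sex, "diagnosis": diagnosis}, index=idx)
    return im.CytokinePanel(vals, meta)


@pytest.fixture
def tiny_panel():
    """3 HC + 2 GWI males, 2 features, one missing cell."""
    return build_panel(
        [[1.0, 2.0], [3.0, 4.0], [5.0, np.nan], [7.0, 8.0], [9.0, 10.0]],
        sex=["male"] * 5,
        diagnosis=["HC", "HC", "HC", "GWI", "GWI"],
        columns=["IL-2_T0", "IL-10_T2"],
    )


@pytest.fixture(scope="session")
def template_panel():
    panel, truth = im.generate(im.study_template())
    return panel, truth
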