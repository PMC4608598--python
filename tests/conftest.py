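import numpy as np
import pandas as pd
import pytest

from antioxkit.io import TimeCourseTable


@pytest.fixture
def tiny_timecourse_frame():
    """Two DPPH series of three time points each, already canonical."""
    rows = []
    for conc, sig in [(10.0, (0.8, 0.6, 0.5)), (20.0, (0.8, 0.5, 0.3))]:
        for t, s in zip((0.0, 60.0, 120.0), sig):
            rows.append(
                dict(assay_id="dpph", compound_id="c1", role="sample",
                     conc_uM=conc, replicate=1, time_s=t, signal=s)
            )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_table(tiny_timecourse_frame):
    return TimeCourseTable(tiny_timecourse_frame)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
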