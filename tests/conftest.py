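import numpy as np
import pandas as pd
import pytest

from enose_driftlab.panel import METADATA_COLUMNS, SensorPanel, sensor_names


def build_panel(
    responses,
    group=None,
    day=None,
    day_vocabulary=None,
    **meta,
):
    """Construct a SensorPanel from a response matrix and per-sample metadata.

    Unspecified metadata falls back to neutral constants so hand-computed
    fixtures stay terse.
    """
    x = np.atleast_2d(np.asarray(responses, dtype=float))
    n, p = x.shape
    cols = sensor_names(p)
    defaults = {
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "group": group if group is not None else ["control"] * n,
        "activity": ["not_applicable"] * n,
        "diet": ["none"] * n,
        "surgery": ["none"] * n,
        "day": day if day is not None else ["day1"] * n,
        "age": [50.0] * n,
        "sex": ["F"] * n,
        "smoking": ["never"] * n,
        "hospital": ["hospA"] * n,
    }
    defaults.update(meta)
    data = pd.DataFrame({k: defaults[k] for k in METADATA_COLUMNS})
    data = pd.concat([data, pd.DataFrame(x, columns=list(cols))], axis=1)
    return SensorPanel(
        data=data,
        sensor_columns=cols,
        day_vocabulary=tuple(day_vocabulary) if day_vocabulary else (),
    )


@pytest.fixture
def panel_factory():
    return build_panel


@pytest.fixture(autouse=True)
def _quiet_selection_warnings(caplog):
    # the fixed-policy leakage warning is intentional and noisy in bulk tests
    import logging

    logging.getLogger("enose_driftlab").setLevel(logging.ERROR)
    yield
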