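import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_tables():
    """Two small, fully valid subjects in the raw CSV schemas."""
    t0 = pd.Timestamp("2023-03-01 08:00:00")
    uo = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b"],
            "timestamp": [t0, t0 + pd.Timedelta(hours=1), t0],
            "volume_ml": [60.0, 55.0, 80.0],
        }
    )
    scr = pd.DataFrame(
        {
            "subject_id": ["a", "b"],
            "timestamp": [t0, t0 + pd.Timedelta(hours=2)],
            "scr_mg_dl": [1.0, 0.9],
        }
    )
    rrt = pd.DataFrame(
        {"subject_id": ["a"], "timestamp": [t0], "active": [False]}
    )
    demo = pd.DataFrame(
        {
            "subject_id": ["a", "b"],
            "weight_kg": [70.0, 82.0],
            "height_cm": [175.0, np.nan],
            "age_years": [61.0, 45.0],
            "sex": ["female", "male"],
        }
    )
    return uo, scr, rrt, demo
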