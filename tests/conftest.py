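import numpy as np
import pandas as pd
import pytest

from vilpa import EpochSeries
from vilpa.simulate import SimConfig, simulate_analysis_cohort, simulate_cohort

#: per-cause baseline hazards scaled up so small test cohorts have events
ELEVATED_HAZARDS = {"cvd": 0.015, "cancer": 0.032, "other_death": 0.004}


def make_series(states, accels, participant_id="p1", start="2015-06-01"):
    """EpochSeries from explicit state/acceleration lists (10-s spacing)."""
    n = len(states)
    ts = pd.to_datetime(np.datetime64(start) + np.arange(n) * np.timedelta64(10, "s"))
    return EpochSeries(
        participant_id,
        pd.DataFrame({"timestamp": ts, "state": states, "accel_mg": accels}),
    )


def day_series(day_states, participant_id="p1", start="2015-06-01"):
    """EpochSeries spanning full days; ``day_states`` is a list of
    (state, accel, n_epochs) run-length blocks per day, each padded with
    nonwear to 8,640 epochs."""
    states, accels = [], []
    for blocks in day_states:
        count = 0
        for state, accel, n in blocks:
            states.extend([state] * n)
            accels.extend([accel] * n)
            count += n
        pad = 8640 - count
        assert pad >= 0, "day overflows 8,640 epochs"
        states.extend(["nonwear"] * pad)
        accels.extend([0.0] * pad)
    return make_series(states, accels, participant_id, start)


@pytest.fixture(scope="session")
def small_cohort():
    """Small full-stack synthetic cohort with elevated mortality so model
    stages have events to work with."""
    cfg = SimConfig(n_participants=12, seed=20, baseline_hazards=dict(ELEVATED_HAZARDS))
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def analysis_frame():
    """Model-tier cohort: exposure + covariates + survival, ~600 events."""
    return simulate_analysis_cohort(4000, seed=101, beta=-0.08, baseline_hazard=0.03)
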