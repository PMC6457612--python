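import numpy as np
import pandas as pd
import pytest

from dynasl import (
    BaselineSpec,
    CohortTable,
    ColumnMeta,
    MissingnessSpec,
    OutcomeSpec,
    SimulationConfig,
    TimeVaryingSpec,
)


def make_config(
    n=200,
    seed=0,
    grid=(0.0, 2.0, 3.0, 4.0),
    death_coefs=None,
    death_intercepts=-2.0,
    extra_outcomes=(),
    missingness=None,
):
    """Small three-interval configuration used across the suite."""
    return SimulationConfig(
        n_patients=n,
        time_grid=grid,
        baseline_specs=[
            BaselineSpec("x1", "continuous", {"mean": 0.0, "sd": 1.0}),
            BaselineSpec("x2", "binary", {"p": 0.4}),
        ],
        timevarying_specs=[
            TimeVaryingSpec("hr", persistence=0.7, noise_scale=1.0, severity_loading=0.8),
        ],
        outcome_specs=[
            OutcomeSpec(
                "death",
                intercepts=death_intercepts,
                coefficients=death_coefs or {},
                terminal=True,
            ),
            *extra_outcomes,
        ],
        missingness_spec=missingness or {},
        seed=seed,
    )


@pytest.fixture
def tiny_table():
    """Three patients, one continuous lab with a missing value."""
    frame = pd.DataFrame(
        {
            "patient_id": [1, 2, 3],
            "age": [30.0, 45.0, 60.0],
            "lactate_t0": [5.1, np.nan, 3.0],
            "death": [0.0, 1.0, 0.0],
            "death_time": [np.nan, 2.5, np.nan],
        }
    )
    meta = {
        "age": ColumnMeta(kind="continuous"),
        "lactate_t0": ColumnMeta(kind="continuous", time=0.0),
        "death": ColumnMeta(kind="binary", role="outcome"),
        "death_time": ColumnMeta(kind="continuous", role="event_time"),
    }
    return CohortTable(frame, meta)


def pairwise_auc_bruteforce(scores, y):
    """Independent oracle: enumerate all (event, non-event) pairs."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    events = scores[y == 1]
    nonevents = scores[y == 0]
    total = 0.0
    for a in events:
        for b in nonevents:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(events) * len(nonevents))
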