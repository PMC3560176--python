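"""Shared fixtures: trajectory builders, calibrated parameter sets, worked logs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from actipheno.cohort import GroupParameterSet, sample_feature_cohort
from actipheno.motion import Trajectory


def make_traj(x, y, fs: float = 50.0, marker: str = "head",
              valid=None) -> Trajectory:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.arange(x.size) / fs
    if valid is None:
        valid = np.ones(x.size, dtype=bool)
    return Trajectory(marker, t, x, y, np.asarray(valid, dtype=bool))


@pytest.fixture(scope="session")
def table_params() -> GroupParameterSet:
    """Group parameters reconstructed from the published summary tables."""
    return GroupParameterSet.from_reference_tables()


@pytest.fixture(scope="session")
def study_cohort(table_params) -> pd.DataFrame:
    """A 40/60 cohort at the published sample sizes, fixed seed."""
    return sample_feature_cohort(table_params, seed=42)


@pytest.fixture(scope="session")
def large_cohort(table_params) -> pd.DataFrame:
    """A 2000/3000 cohort for population-level checks."""
    params = GroupParameterSet.from_reference_tables(n_adhd=2000,
                                                     n_control=3000)
    return sample_feature_cohort(params, seed=7)


@pytest.fixture()
def worked_no4s_log() -> pd.DataFrame:
    """Hand-scored ten-trial log: 9 targets (8 hits, 1 miss), 1 non-target FA.

    Hit latencies are evenly spaced 400..480 ms, so the correct-response
    mean is 440 ms; accuracy 8/10, one omission, one commission.
    """
    rts = np.linspace(400.0, 480.0, 8)
    rows = []
    for i in range(10):
        onset = 2750.0 * i
        if i == 3:          # the single non-target draws a false alarm
            rows.append(("no4s", i, onset, "4", False, True, 350.0))
        elif i == 7:        # one missed target
            rows.append(("no4s", i, onset, "8", True, False, np.nan))
        else:
            rt = rts[len([r for r in rows if r[4] and r[5]])]
            rows.append(("no4s", i, onset, "16", True, True, float(rt)))
    df = pd.DataFrame(rows, columns=["task", "trial_index", "onset_ms",
                                     "stimulus_code", "is_target",
                                     "responded", "rt_ms"])
    df["block"] = pd.NA
    df["sub_block"] = pd.NA
    df["isi_ms"] = 2500.0
    return df
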