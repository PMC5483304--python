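"""Shared fixtures: synthetic cohorts and exactly-linear profile factories."""

import numpy as np
import pytest

from mpalss.profiles import FULL_GRID, GE31, LT31, ConcentrationTimeProfile
from mpalss.simulate import default_config, simulate_cohort

# Trapezoid weight of each grid time in AUC(0-12) on the nine-point grid.
GRID = np.array(FULL_GRID)
TRAP_W = np.array([0.25, 0.5, 0.75, 1.0, 1.0, 1.5, 2.0, 3.0, 2.0])
_SLACK_IDX = 7  # the 8-h sample, weight 3, outside the <=6 h candidate set


def make_profile(concs, patient_id="P", pod=14, dose_mg=750.0, times=FULL_GRID):
    return ConcentrationTimeProfile(
        patient_id=patient_id, pod=pod, dose_mg=dose_mg,
        times_h=tuple(times), concs_ug_ml=tuple(concs))


def make_profiles_with_auc(conc_rows, target_aucs, pods=None):
    """Full-grid profiles whose trapezoidal AUC equals ``target_aucs`` exactly.

    The 8-h concentration (not a candidate sampling time) is solved as the
    slack variable; rows must leave it non-negative.
    """
    out = []
    for i, (row, auc) in enumerate(zip(conc_rows, target_aucs)):
        row = np.array(row, dtype=float)
        row[_SLACK_IDX] = 0.0
        slack = (auc - float(TRAP_W @ row)) / TRAP_W[_SLACK_IDX]
        if slack < 0:
            raise AssertionError("test construction needs a larger target AUC")
        row[_SLACK_IDX] = slack
        pod = 14 if pods is None else pods[i]
        out.append(make_profile(row, patient_id=f"L{i:03d}", pod=pod))
    return out


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def cohort100(config):
    """Study-sized synthetic cohort: 39 early + 61 late profiles, seed 1."""
    return (simulate_cohort(39, LT31, config, seed=1)
            + simulate_cohort(61, GE31, config, seed=1))


@pytest.fixture(scope="session")
def ge_cohort(cohort100):
    return [p for p in cohort100 if p.pod >= 31]
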