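"""Shared fixtures: a calibrated reference burster and cached protocol runs.

Simulation fixtures are session-scoped; everything is generated at test time
from the seeded model code (no stored fixture files).
"""

import numpy as np
import pytest

from dualscale.ensemble import (CALIBRATION_WINDOW_S, reference_model,
                                settle_and_calibrate)
from dualscale.experiments import run_model
from dualscale.ensemble import EnsembleMember
from dualscale.protocol import build_schedule
from dualscale.experiments import PROFILES

DT = 0.05


@pytest.fixture(scope="session")
def reference():
    """(intrinsic, targets, period, settled trace) of the reference burster."""
    intrinsic = reference_model()
    result = settle_and_calibrate(intrinsic, dt=DT)
    assert result is not None, "reference model failed to calibrate"
    targets, period, trace = result
    return intrinsic, targets, period, trace


@pytest.fixture(scope="session")
def reference_member(reference):
    intrinsic, targets, period, trace = reference
    return EnsembleMember(model_id="ref", index=-1, intrinsic=intrinsic,
                          targets=targets, period=period,
                          settled_state=trace.final_state)


@pytest.fixture(scope="session")
def ci_schedule():
    return build_schedule(**PROFILES["ci"])


@pytest.fixture(scope="session")
def ci_runs(reference_member, ci_schedule):
    """Scaled-down protocol runs of the reference model, one per variant."""
    runs = {}
    for variant in ("full", "half_only", "gmax_only"):
        runs[variant] = run_model(reference_member, variant, ci_schedule,
                                  dt=0.1, profile="ci")
    return runs
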