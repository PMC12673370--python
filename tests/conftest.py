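import numpy as np
import pytest
from hypothesis import settings

import mitoflux as mf

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def air_trace_noiseless():
    """Noiseless SUIT run at air saturation with the default truth."""
    truth = mf.TraceGroundTruth(seed=7).noiseless()
    sched = mf.build_suit028_schedule()
    return mf.simulate_respirometry_trace(sched, truth, o2_regime="air"), truth


@pytest.fixture(scope="session")
def ros_run_noiseless():
    """Noiseless low-O2 run with the AmR channel, bracketed calibrations."""
    truth = mf.TraceGroundTruth(seed=11).noiseless()
    sched = mf.build_suit028_schedule(
        sample_time_s=420.0,
        pre_sample_titrations=(120.0, 200.0, 280.0),
        h2o2_titration_interval_s=1200.0,
    )
    trace = mf.simulate_respirometry_trace(sched, truth, o2_regime="normoxic")
    trace = mf.simulate_amr_channel(trace, truth)
    return trace, truth


@pytest.fixture()
def flat_flux_truth():
    """Truth with no biological activity at all (zero-flux identity)."""
    return mf.TraceGroundTruth(
        j_o2_mass={k: 0.0 for k in mf.TraceGroundTruth().j_o2_mass},
        j_rox_mass=0.0,
        j_endogenous_mass=0.0,
        j_h2o2_mass={k: 0.0 for k in mf.TraceGroundTruth().j_h2o2_mass},
        cytc_effect=0.0,
        uncoupler_profile=(1.0, 1.0, 1.0),
        seed=0,
    ).noiseless()
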