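import numpy as np
import pytest

from stopsignal.io import records_to_frame
from stopsignal.simulate import (
    CohortSpec,
    EnvironmentSpec,
    ParticipantParams,
    SessionDesign,
    simulate_cohort,
    simulate_session,
)
from stopsignal.trial_model import DisplayModel


@pytest.fixture(scope="session")
def stationary_params() -> ParticipantParams:
    """A stationary participant with realistic race-model parameters."""
    return ParticipantParams(
        go_mu_ms=400.0,
        go_sigma_ms=60.0,
        go_tau_ms=120.0,
        ssrt_mu_ms=220.0,
        ssrt_sigma_ms=40.0,
    )


@pytest.fixture(scope="session")
def design() -> SessionDesign:
    return SessionDesign()


@pytest.fixture(scope="session")
def display60() -> DisplayModel:
    return DisplayModel(60.0)


@pytest.fixture(scope="session")
def session_frame(stationary_params, design, display60):
    """One full simulated session as a trial table."""
    trials = simulate_session(
        stationary_params, design, display60, seed=123, participant_id="s1"
    )
    return records_to_frame(trials)


@pytest.fixture(scope="session")
def small_cohort_frame():
    """A small two-environment cohort used by pipeline-level tests."""
    cohort = CohortSpec(
        environments={
            "individual": EnvironmentSpec(n=4, go_mu_ms=(362.0, 90.0)),
            "online": EnvironmentSpec(n=4, go_mu_ms=(464.0, 110.0), slowing_slope=(0.8, 0.9)),
        },
        seed=42,
    )
    return simulate_cohort(cohort, SessionDesign(), DisplayModel(60.0))


def make_block(
    go_rts,
    n_stop_respond,
    n_stop_success,
    ssds,
    *,
    participant_id="p1",
    staircase_label="p50",
    phase_index=1,
    block_index=1,
    go_omissions=0,
    signal_respond_rts=None,
):
    """Hand-built trial table for one block: explicit go RTs, stop-trial
    outcomes and intended SSDs.  The analysis modules only consume the
    tabular fields, so rows are assembled directly."""
    import pandas as pd

    rows = []
    t = 0
    for i, rt in enumerate(go_rts, start=1):
        t += 1
        rows.append(
            dict(
                participant_id=participant_id, environment="individual",
                phase_index=phase_index, block_index=block_index, trial_index=t,
                go_trial_index=i, staircase_label=staircase_label,
                trial_type="go", stimulus="left", response="left",
                rt_ms=float(rt), ssd_intended_ms=np.nan, ssd_actual_ms=np.nan,
                stop_success=pd.NA,
            )
        )
    for i in range(go_omissions):
        t += 1
        rows.append(
            dict(
                participant_id=participant_id, environment="individual",
                phase_index=phase_index, block_index=block_index, trial_index=t,
                go_trial_index=len(go_rts) + i + 1, staircase_label=staircase_label,
                trial_type="go", stimulus="left", response="none",
                rt_ms=np.nan, ssd_intended_ms=np.nan, ssd_actual_ms=np.nan,
                stop_success=pd.NA,
            )
        )
    n_stop = n_stop_respond + n_stop_success
    assert len(ssds) == n_stop
    sr_rts = list(signal_respond_rts or [500.0] * n_stop_respond)
    for j in range(n_stop):
        t += 1
        responded = j < n_stop_respond
        rows.append(
            dict(
                participant_id=participant_id, environment="individual",
                phase_index=phase_index, block_index=block_index, trial_index=t,
                go_trial_index=pd.NA, staircase_label=staircase_label,
                trial_type="stop", stimulus="left",
                response="left" if responded else "none",
                rt_ms=sr_rts[j] if responded else np.nan,
                ssd_intended_ms=float(ssds[j]), ssd_actual_ms=float(ssds[j]),
                stop_success=not responded,
            )
        )
    df = pd.DataFrame(rows)
    df["stop_success"] = df["stop_success"].astype("boolean")
    df["go_trial_index"] = df["go_trial_index"].astype("Int64")
    return df
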