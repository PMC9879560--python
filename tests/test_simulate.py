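"""Session and cohort simulation under the independent horse-race model."""

import numpy as np
from scipy import stats

from stopsignal.qc import slowing_slope
from stopsignal.simulate import (
    CohortSpec,
    EnvironmentSpec,
    ParticipantParams,
    simulate_block,
    simulate_cohort,
    simulate_session,
)
from stopsignal.staircase import PRESETS, StaircaseSpec
from stopsignal.trial_model import TrialType


class TestSessionStructure:
    def test_trial_and_stop_counts(self, session_frame):
        assert len(session_frame) == 768
        assert (session_frame["trial_type"] == "stop").sum() == 192
        assert session_frame["phase_index"].nunique() == 4

    def test_same_seed_reproduces_table(self, stationary_params, design, display60):
        a = simulate_session(stationary_params, design, display60, seed=7)
        b = simulate_session(stationary_params, design, display60, seed=7)
        assert a == b

    def test_no_rt_exceeds_response_window(self, session_frame):
        assert session_frame["rt_ms"].dropna().max() <= 1500.0

    def test_phases_alternate_and_reset_staircase(self, session_frame):
        labels = session_frame.groupby("phase_index")["staircase_label"].first()
        assert labels[1] == labels[3] and labels[2] == labels[4]
        assert labels[1] != labels[2]
        first_stop = (
            session_frame[session_frame["trial_type"] == "stop"]
            .groupby("phase_index")
            .first()
        )
        assert (first_stop["ssd_intended_ms"] == 250.0).all()

    def test_go_trial_index_is_sequential_within_block(self, session_frame):
        for _, block in session_frame.groupby(["phase_index", "block_index"]):
            idx = block.loc[block["trial_type"] == "go", "go_trial_index"].tolist()
            assert idx == list(range(1, len(idx) + 1))

    def test_quantized_onsets_never_precede_intended(self, session_frame):
        stop = session_frame[session_frame["trial_type"] == "stop"]
        assert (stop["ssd_actual_ms"] >= stop["ssd_intended_ms"] - 1e-9).all()


class TestDegenerateParameters:
    def test_full_lapse_rate_yields_only_omissions(self, design, display60):
        params = ParticipantParams(
            go_mu_ms=400, go_sigma_ms=60, go_tau_ms=120,
            ssrt_mu_ms=220, ssrt_sigma_ms=40, lapse_rate=1.0,
        )
        trials = simulate_session(params, design, display60, seed=1)
        assert all(t.response.value == "none" for t in trials)

    def test_deterministic_race_every_stop_fails(self, design):
        """Degenerate distributions: go always finishes at 400 ms, stop
        process at SSD 350 + SSRT 150 = 500 ms, so the go response always
        escapes and every stop trial is a failed stop."""
        params = ParticipantParams(
            go_mu_ms=400, go_sigma_ms=0, go_tau_ms=0,
            ssrt_mu_ms=150, ssrt_sigma_ms=0,
        )
        spec = StaircaseSpec("fixed", 1.0, 1.0, initial_ssd_ms=350.0,
                             min_ssd_ms=350.0, max_ssd_ms=350.0)
        res = simulate_block(
            params, spec, spec.initial_state(), design, None,
            np.random.default_rng(0),
        )
        stops = [t for t in res.trials if t.trial_type is TrialType.stop]
        assert len(stops) == 24
        assert all(t.stop_success is False for t in stops)
        assert all(t.rt_ms == 400.0 for t in stops)


class TestRaceModelProperties:
    def test_context_independence_of_go_process(self, stationary_params, design):
        """The latent go finishing-time distribution is the same on go and
        stop trials by construction; a KS test on the latent draws must
        not reject."""
        rng = np.random.default_rng(11)
        spec = PRESETS["p50"]
        state = spec.initial_state()
        go_lat, stop_lat = [], []
        for _ in range(30):
            res = simulate_block(stationary_params, spec, state, design, None, rng)
            state = res.state
            for trial, lat in zip(res.trials, res.latent_go_ms):
                (stop_lat if trial.trial_type is TrialType.stop else go_lat).append(lat)
        p = stats.ks_2samp(go_lat, stop_lat).pvalue
        assert p > 0.01

    def test_staircase_tracks_p50_asymptote(self, stationary_params, design):
        rng = np.random.default_rng(21)
        spec = PRESETS["p50"]
        state = spec.initial_state()
        succ = tot = 0
        for _ in range(60):
            res = simulate_block(stationary_params, spec, state, design, None, rng)
            state = res.state
            for t in res.trials:
                if t.trial_type is TrialType.stop:
                    tot += 1
                    succ += t.stop_success
        se = np.sqrt(0.25 / tot)
        assert abs(succ / tot - 0.5) < 3 * se


class TestCohort:
    def test_bookkeeping_and_reproducibility(self):
        spec = CohortSpec(
            environments={
                "individual": EnvironmentSpec(n=2, go_mu_ms=(360.0, 50.0)),
                "group": EnvironmentSpec(n=2, go_mu_ms=(380.0, 50.0)),
                "online": EnvironmentSpec(n=2, go_mu_ms=(460.0, 50.0)),
            },
            seed=5,
        )
        df = simulate_cohort(spec)
        assert df["participant_id"].nunique() == 6
        assert len(df) == 6 * 768
        df2 = simulate_cohort(spec)
        assert df.equals(df2)

    def test_zero_slope_cohort_has_near_zero_mean_fitted_slope(self):
        spec = CohortSpec(
            environments={
                "individual": EnvironmentSpec(
                    n=6, go_mu_ms=(380.0, 60.0), slowing_slope=(0.0, 0.0)
                )
            },
            seed=9,
        )
        df = simulate_cohort(spec)
        slopes = [
            slowing_slope(block)
            for _, block in df.groupby(["participant_id", "phase_index", "block_index"])
        ]
        assert abs(float(np.nanmean(slopes))) < 0.3


class TestCannedCohorts:
    def test_canned_cohorts_are_deterministic_and_distinct(self):
        from stopsignal.fixtures import CANNED_COHORTS, canned_cohort

        assert set(CANNED_COHORTS) == {"no_slowing", "lab_like", "online_like"}
        a = canned_cohort("no_slowing", n_per_environment=2)
        b = canned_cohort("no_slowing", n_per_environment=2)
        assert a.equals(b)
        online = canned_cohort("online_like", n_per_environment=2)
        assert set(online["environment"]) == {"online"}
        assert len(a) == 2 * 768
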