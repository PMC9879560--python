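"""Seeded simulation of stop-signal sessions and cohorts under the
independent horse-race model.

Go finishing times are ex-Gaussian (normal + exponential), the standard
parametric family for reaction times; SSRTs are drawn from a normal
truncated at zero.  Strategic slowing — participants lengthening go
responses within a block to make stopping easier — is modelled as a linear
drift of the go mean per go trial, reset at block boundaries, matching the
per-block slope criterion used for quality control.

A session comprises four experimental phases of 192 trials (two 96-trial
blocks), 25 % stop trials per block, phases alternating between the p50
and p66 staircases with the staircase reset at each phase start, preceded
by 32 practice trials (excluded from output by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import staircase as sc
from .trial_model import (
    MAX_RT_MS,
    DisplayModel,
    Environment,
    Response,
    Stimulus,
    coerce_staircase_label,
    TrialRecord,
    TrialType,
    quantize_onset,
    run_race,
)

__all__ = [
    "ParticipantParams",
    "SessionDesign",
    "EnvironmentSpec",
    "CohortSpec",
    "BlockResult",
    "simulate_block",
    "simulate_session",
    "simulate_cohort",
    "default_cohort_spec",
]


@dataclass(frozen=True)
class ParticipantParams:
    """Generative race-model parameters for one participant.

    ``go_mu_ms``/``go_sigma_ms`` are the Gaussian component and
    ``go_tau_ms`` the exponential tail of the ex-Gaussian go finishing
    time (mean RT = mu + tau).  SSRT draws are normal(mu, sigma)
    truncated at 0.  ``slowing_slope_ms_per_go_trial`` shifts the go mean
    linearly with the within-block go-trial ordinal (0 = stationary).
    ``lapse_rate`` is the probability the go process never produces a
    response, independent of its latency; ``choice_error_rate`` the
    probability a produced response uses the wrong key.
    """

    go_mu_ms: float
    go_sigma_ms: float
    go_tau_ms: float
    ssrt_mu_ms: float
    ssrt_sigma_ms: float
    slowing_slope_ms_per_go_trial: float = 0.0
    lapse_rate: float = 0.0
    choice_error_rate: float = 0.0
    trigger_failure_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.go_sigma_ms, self.go_tau_ms, self.ssrt_sigma_ms) < 0:
            raise ValueError("scale parameters must be non-negative")
        for r in (self.lapse_rate, self.choice_error_rate, self.trigger_failure_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class SessionDesign:
    """Session layout: phases, blocks, trial counts and timing constants."""

    n_phases: int = 4
    blocks_per_phase: int = 2
    trials_per_block: int = 96
    stop_proportion: float = 0.25
    practice_trials: int = 32
    staircase_order: str = "randomized"   # p50_first | p66_first | randomized
    max_rt_ms: float = MAX_RT_MS
    fixation_ms: float = 500.0

    def __post_init__(self) -> None:
        n_stop = self.trials_per_block * self.stop_proportion
        if abs(n_stop - round(n_stop)) > 1e-9:
            raise ValueError(
                "trials_per_block * stop_proportion must be an integer"
            )
        if self.staircase_order not in ("p50_first", "p66_first", "randomized"):
            raise ValueError(f"unknown staircase_order {self.staircase_order!r}")

    @property
    def stop_trials_per_block(self) -> int:
        return round(self.trials_per_block * self.stop_proportion)


@dataclass(frozen=True)
class BlockResult:
    """Trials of one block plus the final staircase state and the latent
    process draws (useful as a parameter-recovery oracle)."""

    trials: list[TrialRecord]
    state: sc.StaircaseState
    latent_go_ms: np.ndarray      # one per trial, go and stop alike
    latent_ssrt_ms: np.ndarray    # one per stop trial


def _draw_ex_gaussian(rng: np.random.Generator, mu: float, sigma: float, tau: float) -> float:
    x = rng.normal(mu, sigma) if sigma > 0 else mu
    if tau > 0:
        x += rng.exponential(tau)
    return max(x, 0.0)


def _draw_truncated_normal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    # Truncation at zero; with realistic SSRT parameters rejection is rare.
    if sigma == 0:
        return max(mu, 0.0)
    x = rng.normal(mu, sigma)
    while x < 0:
        x = rng.normal(mu, sigma)
    return x


def simulate_block(
    params: ParticipantParams,
    spec: sc.StaircaseSpec,
    state: sc.StaircaseState,
    design: SessionDesign,
    display: Optional[DisplayModel],
    rng: np.random.Generator,
    *,
    participant_id: str = "sim",
    environment: Environment = Environment.individual,
    phase_index: int = 1,
    block_index: int = 1,
) -> BlockResult:
    """Simulate one block of trials, threading the staircase state through.

    Stop trials occupy seeded-random positions.  Every trial draws a latent
    go finishing time from the same (possibly drifting) distribution —
    context independence holds by construction.  Pass ``display=None`` to
    disable refresh quantization (onsets equal intended SSDs).
    """
    n = design.trials_per_block
    n_stop = design.stop_trials_per_block
    stop_positions = set(rng.choice(n, size=n_stop, replace=False).tolist())

    trials: list[TrialRecord] = []
    latent_go: list[float] = []
    latent_ssrt: list[float] = []
    go_ordinal = 0

    for i in range(n):
        is_stop = i in stop_positions
        # Drift indexed by the go-trial ordinal; stop trials sit at the
        # current drift level (number of go trials completed so far).
        drift_index = go_ordinal if is_stop else go_ordinal + 1
        mu_t = params.go_mu_ms + params.slowing_slope_ms_per_go_trial * (drift_index - 1)
        go_finish = _draw_ex_gaussian(rng, mu_t, params.go_sigma_ms, params.go_tau_ms)
        latent_go.append(go_finish)
        lapse = rng.random() < params.lapse_rate
        stimulus = Stimulus.left if rng.random() < 0.5 else Stimulus.right
        wrong_key = rng.random() < params.choice_error_rate

        common = dict(
            participant_id=participant_id,
            environment=environment,
            phase_index=phase_index,
            block_index=block_index,
            trial_index=i + 1,
            staircase_label=coerce_staircase_label(spec.label),
            stimulus=stimulus,
        )

        if not is_stop:
            go_ordinal += 1
            responded = (not lapse) and go_finish <= design.max_rt_ms
            response = _pick_response(stimulus, wrong_key) if responded else Response.none
            trials.append(
                TrialRecord(
                    trial_type=TrialType.go,
                    go_trial_index=go_ordinal,
                    response=response,
                    rt_ms=go_finish if responded else None,
                    **common,
                )
            )
        else:
            intended = state.current_ssd_ms
            actual = quantize_onset(intended, display) if display is not None else intended
            ssrt_draw = _draw_truncated_normal(rng, params.ssrt_mu_ms, params.ssrt_sigma_ms)
            latent_ssrt.append(ssrt_draw)
            if lapse:
                responded = False
            elif rng.random() < params.trigger_failure_rate:
                responded = go_finish <= design.max_rt_ms
            else:
                responded = run_race(go_finish, actual, ssrt_draw, design.max_rt_ms).responded
            response = _pick_response(stimulus, wrong_key) if responded else Response.none
            trials.append(
                TrialRecord(
                    trial_type=TrialType.stop,
                    response=response,
                    rt_ms=go_finish if responded else None,
                    ssd_intended_ms=intended,
                    ssd_actual_ms=actual,
                    stop_success=not responded,
                    **common,
                )
            )
            state = sc.update(state, spec, stop_success=not responded)

    return BlockResult(
        trials=trials,
        state=state,
        latent_go_ms=np.asarray(latent_go),
        latent_ssrt_ms=np.asarray(latent_ssrt),
    )


def _pick_response(stimulus: Stimulus, wrong_key: bool) -> Response:
    correct = Response(stimulus.value)
    if not wrong_key:
        return correct
    return Response.right if correct is Response.left else Response.left


def _phase_labels(design: SessionDesign, rng: np.random.Generator) -> list[str]:
    if design.staircase_order == "p50_first":
        first, second = "p50", "p66"
    elif design.staircase_order == "p66_first":
        first, second = "p66", "p50"
    else:
        first, second = ("p50", "p66") if rng.random() < 0.5 else ("p66", "p50")
    return [first if p % 2 == 0 else second for p in range(design.n_phases)]


def simulate_session(
    params: ParticipantParams,
    design: SessionDesign = SessionDesign(),
    display: Optional[DisplayModel] = DisplayModel(),
    seed: int | np.random.SeedSequence = 0,
    *,
    participant_id: str = "sim",
    environment: Environment = Environment.individual,
    include_practice: bool = False,
    specs: Optional[dict[str, sc.StaircaseSpec]] = None,
) -> list[TrialRecord]:
    """Simulate a full session: phases alternate staircases, each phase
    restarting its staircase from the initial SSD.

    Practice trials (``design.practice_trials``, same stop proportion,
    run on the first phase's staircase) are simulated but dropped from the
    output unless ``include_practice`` is set; they are emitted with
    ``phase_index=0``.
    """
    rng = np.random.default_rng(seed)
    specs = specs or sc.PRESETS
    labels = _phase_labels(design, rng)
    out: list[TrialRecord] = []

    if design.practice_trials > 0:
        practice_design = replace(
            design,
            trials_per_block=design.practice_trials,
        )
        spec = specs[labels[0]]
        res = simulate_block(
            params, spec, spec.initial_state(), practice_design, display, rng,
            participant_id=participant_id, environment=environment,
            phase_index=0, block_index=1,
        )
        if include_practice:
            out.extend(res.trials)

    for phase in range(1, design.n_phases + 1):
        spec = specs[labels[phase - 1]]
        state = spec.initial_state()
        for block in range(1, design.blocks_per_phase + 1):
            res = simulate_block(
                params, spec, state, design, display, rng,
                participant_id=participant_id, environment=environment,
                phase_index=phase, block_index=block,
            )
            state = res.state
            out.extend(res.trials)
    return out


@dataclass(frozen=True)
class EnvironmentSpec:
    """Between-participant parameter distributions for one testing
    environment: each field is a (mean, sd) pair for the corresponding
    ``ParticipantParams`` field, sampled normally and clipped to validity."""

    n: int
    go_mu_ms: tuple[float, float]
    go_sigma_ms: tuple[float, float] = (60.0, 10.0)
    go_tau_ms: tuple[float, float] = (150.0, 30.0)
    ssrt_mu_ms: tuple[float, float] = (245.0, 40.0)
    ssrt_sigma_ms: tuple[float, float] = (45.0, 10.0)
    slowing_slope: tuple[float, float] = (0.0, 0.0)
    lapse_rate: tuple[float, float] = (0.01, 0.01)
    choice_error_rate: tuple[float, float] = (0.01, 0.01)

    def draw_params(self, rng: np.random.Generator) -> ParticipantParams:
        def normal(pair: tuple[float, float], lo: float = 0.0, hi: float = np.inf) -> float:
            m, s = pair
            return float(np.clip(rng.normal(m, s) if s > 0 else m, lo, hi))

        return ParticipantParams(
            go_mu_ms=normal(self.go_mu_ms, lo=100.0),
            go_sigma_ms=normal(self.go_sigma_ms, lo=1.0),
            go_tau_ms=normal(self.go_tau_ms, lo=1.0),
            ssrt_mu_ms=normal(self.ssrt_mu_ms, lo=80.0),
            ssrt_sigma_ms=normal(self.ssrt_sigma_ms, lo=1.0),
            slowing_slope_ms_per_go_trial=normal(self.slowing_slope, lo=-np.inf),
            lapse_rate=normal(self.lapse_rate, hi=1.0),
            choice_error_rate=normal(self.choice_error_rate, hi=1.0),
        )


@dataclass(frozen=True)
class CohortSpec:
    """Per-environment sample sizes and parameter distributions."""

    environments: dict[str, EnvironmentSpec] = field(default_factory=dict)
    seed: int = 0


def default_cohort_spec(seed: int = 0, n_per_environment: int = 40) -> CohortSpec:
    """Cohort emulating the three testing environments.

    Mean go RT (mu + tau) is set to roughly 510 ms for individual lab
    testing, 530 ms for group lab testing and 615 ms online, with online
    participants also drifting (strategically slowing) more within blocks
    — the pattern of lower supervision producing slower, less stable
    responding.
    """
    return CohortSpec(
        environments={
            "individual": EnvironmentSpec(
                n=n_per_environment, go_mu_ms=(362.0, 90.0), slowing_slope=(0.2, 0.6)
            ),
            "group": EnvironmentSpec(
                n=n_per_environment, go_mu_ms=(383.0, 100.0), slowing_slope=(0.3, 0.6)
            ),
            "online": EnvironmentSpec(
                n=n_per_environment, go_mu_ms=(464.0, 110.0), slowing_slope=(0.8, 0.9)
            ),
        },
        seed=seed,
    )


def simulate_cohort(
    cohort: CohortSpec,
    design: SessionDesign = SessionDesign(),
    display: Optional[DisplayModel] = DisplayModel(),
) -> pd.DataFrame:
    """Simulate every participant of a cohort; returns one tidy trial table.

    Participant parameters are drawn from their environment's
    distributions; all randomness descends from ``cohort.seed`` so the
    table is bit-reproducible.
    """
    from .io import records_to_frame

    root = np.random.SeedSequence(cohort.seed)
    frames: list[pd.DataFrame] = []
    env_items = sorted(cohort.environments.items())
    env_seeds = root.spawn(len(env_items))
    for (env_name, env_spec), env_seed in zip(env_items, env_seeds):
        env = Environment(env_name)
        param_rng = np.random.default_rng(env_seed)
        session_seeds = env_seed.spawn(env_spec.n)
        for i in range(env_spec.n):
            params = env_spec.draw_params(param_rng)
            pid = f"{env_name}_{i + 1:03d}"
            trials = simulate_session(
                params, design, display, seed=session_seeds[i],
                participant_id=pid, environment=env,
            )
            frames.append(records_to_frame(trials))
    if not frames:
        return records_to_frame([])
    return pd.concat(frames, ignore_index=True)
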