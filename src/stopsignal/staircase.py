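"""Generalized up/down SSD staircase.

After every stop trial the stop-signal delay (SSD) moves up (harder to
stop) following a successful stop and down (easier) following a failed
stop.  A staircase with post-success step ``d_s`` and post-failure step
``d_f`` equilibrates where the expected one-step SSD change is zero,

    p_stop * d_s - (1 - p_stop) * d_f = 0,

so the asymptotic stopping accuracy is ``d_f / (d_f + d_s)``: the classic
symmetric +/-50 ms staircase tracks 50 %, while a +25/-50 staircase tracks
66.67 %.

On a real monitor the post-success increment is inflated whenever it moves
the SSD off a frame boundary: at 60 Hz a +25 ms step lands off-frame half
the time and is displayed 8.33 ms late, so the *effective* mean increment
is 29.17 ms and the +25/-50 staircase tends to a slightly lower accuracy
of 63.16 %.  ``effective_asymptote`` reproduces that arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

from .trial_model import DisplayModel, _frac_gcd, mean_display_delay

__all__ = [
    "StaircaseSpec",
    "StaircaseState",
    "PRESETS",
    "get_preset",
    "update",
    "predict_asymptote",
    "effective_asymptote",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StaircaseSpec:
    """SSD adjustment rule: step sizes (ms), start value and bounds."""

    label: str
    delta_success_ms: float
    delta_fail_ms: float
    initial_ssd_ms: float = 250.0
    min_ssd_ms: float = 0.0
    max_ssd_ms: float = 1150.0

    def __post_init__(self) -> None:
        if self.delta_success_ms <= 0 or self.delta_fail_ms <= 0:
            raise ValueError("staircase step sizes must be positive")
        if not (0 <= self.min_ssd_ms <= self.initial_ssd_ms <= self.max_ssd_ms):
            raise ValueError(
                "require 0 <= min_ssd_ms <= initial_ssd_ms <= max_ssd_ms"
            )

    def initial_state(self) -> "StaircaseState":
        return StaircaseState(current_ssd_ms=self.initial_ssd_ms)


@dataclass(frozen=True)
class StaircaseState:
    current_ssd_ms: float
    n_success: int = 0
    n_fail: int = 0


#: The two staircases used in the session design: a symmetric +/-50 ms
#: staircase tracking 50 % stopping accuracy, and a +25/-50 ms staircase
#: tracking 66.67 %.  Both start at 250 ms.
PRESETS: dict[str, StaircaseSpec] = {
    "p50": StaircaseSpec("p50", delta_success_ms=50.0, delta_fail_ms=50.0),
    "p66": StaircaseSpec("p66", delta_success_ms=25.0, delta_fail_ms=50.0),
}


def get_preset(name: str) -> StaircaseSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown staircase preset {name!r}; choose from {sorted(PRESETS)}")


def update(state: StaircaseState, spec: StaircaseSpec, stop_success: bool) -> StaircaseState:
    """Advance the staircase after one stop trial.

    SSD increases by ``delta_success_ms`` after a successful stop and
    decreases by ``delta_fail_ms`` after a failed one, clamped to the
    spec's bounds; clamping events are logged.
    """
    if stop_success:
        ssd = state.current_ssd_ms + spec.delta_success_ms
    else:
        ssd = state.current_ssd_ms - spec.delta_fail_ms
    clamped = min(max(ssd, spec.min_ssd_ms), spec.max_ssd_ms)
    if clamped != ssd:
        logger.info(
            "staircase %s clamped: %g -> %g ms", spec.label, ssd, clamped
        )
    return replace(
        state,
        current_ssd_ms=clamped,
        n_success=state.n_success + int(stop_success),
        n_fail=state.n_fail + int(not stop_success),
    )


def predict_asymptote(spec: StaircaseSpec) -> float:
    """Asymptotic stopping accuracy d_fail / (d_fail + d_success)."""
    denom = spec.delta_fail_ms + spec.delta_success_ms
    if denom <= 0:
        raise ValueError("step sizes must be positive")
    return spec.delta_fail_ms / denom


def effective_asymptote(spec: StaircaseSpec, display: DisplayModel) -> float:
    """Asymptote after refresh quantization inflates the post-success step.

    The staircase confines SSDs to a lattice whose pitch is the gcd of the
    step sizes and the start/bound values; the mean quantization delay on
    that lattice is added to the post-success step before applying the
    asymptote formula.  At 60 Hz the +25/-50 staircase has a 25 ms lattice
    with mean delay 4.17 ms, hence an effective +29.17 ms step and an
    asymptote of 63.16 %.
    """
    step = _ssd_lattice_step(spec)
    delay = mean_display_delay(float(step), display)
    effective = replace(spec, delta_success_ms=spec.delta_success_ms + delay)
    return predict_asymptote(effective)


def _ssd_lattice_step(spec: StaircaseSpec) -> Fraction:
    values = [
        spec.delta_success_ms,
        spec.delta_fail_ms,
        spec.initial_ssd_ms,
        spec.min_ssd_ms,
        spec.max_ssd_ms,
    ]
    g = Fraction(0)
    for v in values:
        if v != 0:
            g = _frac_gcd(g, Fraction(v)) if g else Fraction(v)
    return g
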