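"""Core domain types for stop-signal task (SST) trials, the single-trial
horse-race outcome rule, and the monitor-refresh quantization model of
stop-signal onset.

The stop-signal task presents a speeded two-choice "go" stimulus on every
trial; on a minority of trials a stop signal follows after a stop-signal
delay (SSD) and the response must be withheld.  Under the independent
horse-race model, a response is emitted if and only if the latent go
process finishes before the stop process (SSD + stop-signal reaction
time, SSRT) and within the response window.

Because stimulus onsets are locked to monitor refreshes, an intended SSD
that does not fall on a frame boundary is displayed late: at 60 Hz the
frame lasts 16.67 ms, so an SSD of 175 ms is shown at 183.33 ms.  The
quantization operations here model that snapping exactly, in rational
arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Optional

__all__ = [
    "Environment",
    "StaircaseLabel",
    "TrialType",
    "Stimulus",
    "Response",
    "TrialRecord",
    "DisplayModel",
    "RaceOutcome",
    "quantize_onset",
    "mean_display_delay",
    "run_race",
    "MAX_RT_MS",
]

#: Maximal response time: the go stimulus stays on screen this long.
MAX_RT_MS = 1500.0

# Tolerance (ms) for deciding that an intended SSD already sits on a frame
# boundary; guards against float round-trip misclassification.
_FRAME_TOL_MS = Fraction(1, 10**9)


class Environment(str, Enum):
    individual = "individual"
    group = "group"
    online = "online"


class StaircaseLabel(str, Enum):
    p50 = "p50"
    p66 = "p66"


def coerce_staircase_label(label) -> "StaircaseLabel | str":
    """Map preset names onto the enum; custom staircase labels pass
    through as plain strings."""
    try:
        return StaircaseLabel(label)
    except ValueError:
        return str(label)


class TrialType(str, Enum):
    go = "go"
    stop = "stop"


class Stimulus(str, Enum):
    left = "left"
    right = "right"


class Response(str, Enum):
    left = "left"
    right = "right"
    none = "none"


@dataclass(frozen=True)
class TrialRecord:
    """One trial of an SST session.

    Timing fields are in milliseconds from go-signal onset.  SSD fields are
    present only on stop trials; ``ssd_actual_ms`` is the refresh-quantized
    onset and is never earlier than ``ssd_intended_ms``.
    """

    participant_id: str
    environment: Environment
    phase_index: int          # 1..4
    block_index: int          # 1..2 within phase
    trial_index: int          # 1..96 within block
    staircase_label: "StaircaseLabel | str"
    trial_type: TrialType
    stimulus: Stimulus
    response: Response
    go_trial_index: Optional[int] = None   # ordinal among go trials in block
    rt_ms: Optional[float] = None
    ssd_intended_ms: Optional[float] = None
    ssd_actual_ms: Optional[float] = None
    stop_success: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.trial_type is TrialType.go:
            if self.ssd_intended_ms is not None or self.ssd_actual_ms is not None:
                raise ValueError("go trial must not carry SSD fields")
            if self.stop_success is not None:
                raise ValueError("go trial must not carry stop_success")
            if self.go_trial_index is None:
                raise ValueError("go trial requires go_trial_index")
        else:
            if self.ssd_intended_ms is None or self.ssd_actual_ms is None:
                raise ValueError("stop trial requires both SSD fields")
            if self.ssd_actual_ms < self.ssd_intended_ms - 1e-9:
                raise ValueError("ssd_actual_ms must be >= ssd_intended_ms")
            if self.stop_success is None:
                raise ValueError("stop trial requires stop_success")
            if self.stop_success != (self.response is Response.none):
                raise ValueError("stop_success must mirror response absence")
        if (self.response is Response.none) != (self.rt_ms is None):
            raise ValueError("rt_ms present iff a response was made")
        if self.rt_ms is not None and not (0.0 <= self.rt_ms <= MAX_RT_MS):
            raise ValueError(f"rt_ms {self.rt_ms} outside [0, {MAX_RT_MS}]")


@dataclass(frozen=True)
class DisplayModel:
    """A monitor with a fixed refresh rate; frame time kept as a rational."""

    refresh_hz: float = 60.0
    frame: Fraction = field(init=False)

    def __post_init__(self) -> None:
        if self.refresh_hz <= 0:
            raise ValueError("refresh_hz must be positive")
        object.__setattr__(self, "frame", Fraction(1000) / Fraction(self.refresh_hz))

    @property
    def frame_ms(self) -> float:
        return float(self.frame)


@dataclass(frozen=True)
class RaceOutcome:
    """Result of one go-versus-stop race."""

    responded: bool
    finishing_go_ms: float
    finishing_stop_ms: float
    rt_ms: Optional[float] = None


def quantize_onset(intended_ssd: float, display: DisplayModel) -> float:
    """Snap an intended SSD to the first refresh at or after it.

    The go signal is assumed frame-aligned at t=0, so the stop signal can
    only appear at non-negative integer multiples of the frame time.  The
    mapping is idempotent and the identity on exact frame multiples.
    """
    if intended_ssd < 0:
        raise ValueError("intended_ssd must be non-negative")
    frames = (Fraction(intended_ssd) - _FRAME_TOL_MS) / display.frame
    k = max(0, math.ceil(frames))
    return float(k * display.frame)


def mean_display_delay(ssd_grid_step: float, display: DisplayModel) -> float:
    """Average onset delay over one full period of the SSD lattice.

    A staircase confines SSDs to the lattice {0, step, 2*step, ...}; the
    pattern of quantization delays repeats with period lcm(step, frame).
    At 60 Hz with a 25 ms step, half the lattice points are frame-exact
    and half are displayed 8.33 ms late, so the mean delay is 4.17 ms.
    """
    if ssd_grid_step <= 0:
        raise ValueError("ssd_grid_step must be positive")
    step = Fraction(ssd_grid_step)
    g = _frac_gcd(step, display.frame)
    period = step * display.frame / g          # lcm of the two rationals
    n_points = period / step
    assert n_points.denominator == 1
    n = int(n_points)
    total = Fraction(0)
    for i in range(n):
        s = i * step
        k = (s / display.frame).__ceil__()
        total += k * display.frame - s
    return float(total / n)


def run_race(
    go_finish: float,
    ssd_actual: float,
    ssrt_draw: float,
    max_rt: float = MAX_RT_MS,
) -> RaceOutcome:
    """Deterministic comparator embodying the independent race assumption.

    A response occurs iff the go process finishes strictly before the stop
    process (``ssd_actual + ssrt_draw``) and within the response window.
    """
    if min(go_finish, ssd_actual, ssrt_draw, max_rt) < 0:
        raise ValueError("race inputs must be non-negative")
    stop_finish = ssd_actual + ssrt_draw
    responded = go_finish < stop_finish and go_finish <= max_rt
    return RaceOutcome(
        responded=responded,
        finishing_go_ms=go_finish,
        finishing_stop_ms=stop_finish,
        rt_ms=go_finish if responded else None,
    )


def _frac_gcd(a: Fraction, b: Fraction) -> Fraction:
    return Fraction(
        math.gcd(a.numerator * b.denominator, b.numerator * a.denominator),
        a.denominator * b.denominator,
    )
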