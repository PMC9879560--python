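"""Stop-signal reaction time (SSRT) estimation.

The integration method treats the go RT distribution as the finishing-time
distribution of the go process: the probability of responding on stop
trials, p(respond|signal), picks out the nth fastest go RT (n = ceil(p*N)
over the N valid go RTs), and SSRT is that rank-selected RT minus the mean
SSD.  The mean method — mean go RT minus mean SSD — is provided for
comparison; it inflates SSRT whenever stop accuracy exceeds 50 % because
the mean SSD is then shorter while the go RT distribution is unchanged.

Go omissions are excluded from the go RT distribution by default; an
optional replacement rule substitutes the maximum observed go RT for each
omission.  Mean SSD uses the *intended* (recorded) delays, not the
refresh-quantized onsets, mirroring how task software logs SSDs.

Aggregation: a phase's SSRT is the mean of its two block estimates and is
only defined when both blocks survive quality control (one excluded block
leaves too few stop trials).  At the staircase level the two phases are
averaged, with a single surviving phase given full weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SSRTEstimate",
    "SSRTEstimationError",
    "integration_ssrt",
    "mean_method_ssrt",
    "estimate_blocks",
    "aggregate_phase",
    "aggregate_phases",
    "aggregate_staircase",
    "block_go_rt_mean",
]


class SSRTEstimationError(ValueError):
    """Block lacks the stop trials or go RTs needed for an estimate."""


@dataclass(frozen=True)
class SSRTEstimate:
    """Block-level SSRT with its ingredients."""

    level: str                      # block | phase | staircase
    method: str                     # integration | mean
    p_respond_signal: float
    n_go_rts: int
    nth_go_rt_ms: Optional[float]
    mean_ssd_ms: float
    ssrt_ms: float


def _split_block(block: pd.DataFrame, replace_omissions: bool):
    stop = block[block["trial_type"] == "stop"]
    go = block[block["trial_type"] == "go"]
    if len(stop) == 0:
        raise SSRTEstimationError("block has no stop trials")
    go_rts = go["rt_ms"].dropna().to_numpy(dtype=float)
    if replace_omissions and len(go_rts):
        n_omit = int(go["rt_ms"].isna().sum())
        go_rts = np.concatenate([go_rts, np.full(n_omit, go_rts.max())])
    if len(go_rts) == 0:
        raise SSRTEstimationError("block has no go responses")
    p_respond = float((~stop["stop_success"].astype(bool)).mean())
    mean_ssd = float(stop["ssd_intended_ms"].mean())
    return go_rts, p_respond, mean_ssd


def integration_ssrt(block: pd.DataFrame, *, replace_omissions: bool = False) -> SSRTEstimate:
    """Integration-method SSRT for one block of trials.

    n = ceil(p * N) with 1-based ranks, clamped to [1, N]; omitted go
    trials are dropped unless ``replace_omissions`` substitutes the
    maximum go RT for each.
    """
    go_rts, p_respond, mean_ssd = _split_block(block, replace_omissions)
    go_sorted = np.sort(go_rts)
    n_go = len(go_sorted)
    rank = min(max(math.ceil(p_respond * n_go), 1), n_go)
    nth = float(go_sorted[rank - 1])
    return SSRTEstimate(
        level="block",
        method="integration",
        p_respond_signal=p_respond,
        n_go_rts=n_go,
        nth_go_rt_ms=nth,
        mean_ssd_ms=mean_ssd,
        ssrt_ms=nth - mean_ssd,
    )


def mean_method_ssrt(block: pd.DataFrame, *, replace_omissions: bool = False) -> SSRTEstimate:
    """Mean-method SSRT: mean go RT (responses only) minus mean SSD."""
    go_rts, p_respond, mean_ssd = _split_block(block, replace_omissions)
    mean_go = float(np.mean(go_rts))
    return SSRTEstimate(
        level="block",
        method="mean",
        p_respond_signal=p_respond,
        n_go_rts=len(go_rts),
        nth_go_rt_ms=None,
        mean_ssd_ms=mean_ssd,
        ssrt_ms=mean_go - mean_ssd,
    )


_BLOCK_KEYS = ["participant_id", "environment", "staircase_label", "phase_index", "block_index"]


def estimate_blocks(
    trials: pd.DataFrame,
    method: str = "integration",
    *,
    replace_omissions: bool = False,
) -> pd.DataFrame:
    """One SSRT estimate per (participant, staircase, phase, block).

    Blocks that cannot be estimated (no stop trials or no go responses)
    are emitted with ``ssrt_ms`` missing and ``estimable=False``.
    """
    if method not in ("integration", "mean"):
        raise ValueError(f"unknown method {method!r}")
    fn = integration_ssrt if method == "integration" else mean_method_ssrt
    rows = []
    for keys, block in trials.groupby(_BLOCK_KEYS, sort=True, observed=True):
        row = dict(zip(_BLOCK_KEYS, keys))
        try:
            est = fn(block, replace_omissions=replace_omissions)
            row.update(
                method=est.method,
                p_respond_signal=est.p_respond_signal,
                n_go_rts=est.n_go_rts,
                nth_go_rt_ms=est.nth_go_rt_ms,
                mean_ssd_ms=est.mean_ssd_ms,
                ssrt_ms=est.ssrt_ms,
                estimable=True,
            )
        except SSRTEstimationError:
            row.update(
                method=method,
                p_respond_signal=np.nan,
                n_go_rts=0,
                nth_go_rt_ms=np.nan,
                mean_ssd_ms=np.nan,
                ssrt_ms=np.nan,
                estimable=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_phase(block_ssrts: list[float], block_retained: list[bool]) -> Optional[float]:
    """Phase SSRT = mean of its block SSRTs, defined only if every block
    was retained; otherwise the phase is excluded (returns None)."""
    if not all(block_retained) or not block_ssrts:
        return None
    return float(np.mean(block_ssrts))


def aggregate_phases(
    block_estimates: pd.DataFrame,
    *,
    retained_col: str = "retained",
) -> pd.DataFrame:
    """Roll block estimates up to phases.

    If ``retained_col`` is absent every block counts as retained.  A phase
    with any non-retained (or non-estimable) block gets a missing SSRT.
    """
    df = block_estimates.copy()
    if retained_col not in df.columns:
        df[retained_col] = True
    df[retained_col] = df[retained_col] & df.get("estimable", True)
    keys = ["participant_id", "environment", "staircase_label", "phase_index"]
    rows = []
    for k, grp in df.groupby(keys, sort=True, observed=True):
        row = dict(zip(keys, k))
        ssrt = aggregate_phase(
            grp["ssrt_ms"].tolist(), grp[retained_col].astype(bool).tolist()
        )
        row["ssrt_ms"] = np.nan if ssrt is None else ssrt
        row["retained"] = ssrt is not None
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_staircase(phase_estimates: pd.DataFrame) -> pd.DataFrame:
    """Average the two phases of each staircase per participant.

    When one phase is excluded, the surviving phase is given 100 %
    weighting; when both are excluded the value is missing.
    """
    keys = ["participant_id", "environment", "staircase_label"]
    rows = []
    for k, grp in phase_estimates.groupby(keys, sort=True, observed=True):
        vals = grp.loc[grp["retained"].astype(bool), "ssrt_ms"].dropna()
        row = dict(zip(keys, k))
        row["ssrt_ms"] = float(vals.mean()) if len(vals) else np.nan
        row["n_phases_used"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def block_go_rt_mean(block: pd.DataFrame) -> float:
    """Mean go RT over responded go trials of a block."""
    go = block[(block["trial_type"] == "go")]["rt_ms"].dropna()
    return float(go.mean()) if len(go) else float("nan")
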