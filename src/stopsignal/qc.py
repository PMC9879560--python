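"""Quality-control exclusion pipeline for stop-signal data.

Rules (all strict inequalities; boundary values are retained):

* participant: overall go accuracy < 70 %, or an adherence screen for
  near-zero overall stop accuracy;
* block: stop accuracy < 25 %, or a strategic-slowing slope (OLS fit of
  go RT against the within-block go-trial ordinal) greater than
  2 ms per go trial;
* phase: race-model violation (mean go RT below the mean signal-respond
  RT), SSRT below the 100 ms plausibility floor, or either block of the
  phase excluded (too few stop trials remain for a block-level estimate).

Strategic slowing — deliberately lengthening go responses to make
stopping easier — inflates SSRT estimates; a slope just under
2 ms per go trial accumulates to ~140 ms of slowing across a 96-trial
block, which is why blocks above that threshold are discarded rather
than corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ssrt import aggregate_phases

__all__ = [
    "QCConfig",
    "ExclusionReport",
    "slowing_slope",
    "apply_exclusions",
    "exclusion_chisq",
    "excluded_block_counts",
]

logger = logging.getLogger(__name__)

# Strict-inequality thresholds are compared with a small numeric guard so
# that data sitting exactly on a boundary (e.g. a fitted slope of exactly
# 2 ms/go-trial) are retained despite float rounding in the OLS fit.
_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class QCConfig:
    min_block_stop_accuracy: float = 0.25
    min_phase_ssrt_ms: float = 100.0
    min_participant_go_accuracy: float = 0.70
    max_slowing_slope_ms_per_go_trial: float = 2.0
    # adherence screen: participants whose overall stop accuracy is this
    # low did not attempt to stop at all
    min_participant_stop_accuracy: float = 0.01

    def __post_init__(self) -> None:
        for v in (
            self.min_block_stop_accuracy,
            self.min_phase_ssrt_ms,
            self.min_participant_go_accuracy,
            self.max_slowing_slope_ms_per_go_trial,
        ):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("QC thresholds must be finite and positive")


@dataclass(frozen=True)
class ExclusionReport:
    unit: str                 # block | phase | participant
    participant_id: str
    staircase_label: str | None
    phase_index: int | None
    block_index: int | None
    rule: str                 # stop_accuracy | slowing_slope | race_violation
    #                         # | ssrt_floor | go_accuracy | task_adherence
    observed_value: float
    triggered: bool


def slowing_slope(block: pd.DataFrame) -> float:
    """OLS slope of go RT against the go-trial ordinal, in ms per go trial.

    Only responded go trials enter the fit.  Undefined (NaN) with fewer
    than two usable go RTs.
    """
    go = block[(block["trial_type"] == "go") & block["rt_ms"].notna()]
    if len(go) < 2:
        return float("nan")
    x = go["go_trial_index"].to_numpy(dtype=float)
    y = go["rt_ms"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return float("nan")
    return float(np.polyfit(x, y, 1)[0])


def _participant_rules(trials: pd.DataFrame, cfg: QCConfig) -> list[dict]:
    rows = []
    for pid, grp in trials.groupby("participant_id", sort=True):
        go = grp[grp["trial_type"] == "go"]
        stop = grp[grp["trial_type"] == "stop"]
        go_acc = float((go["response"] == go["stimulus"]).mean()) if len(go) else np.nan
        stop_acc = float(stop["stop_success"].astype(bool).mean()) if len(stop) else np.nan
        rows.append(
            dict(
                unit="participant", participant_id=pid, staircase_label=None,
                phase_index=None, block_index=None, rule="go_accuracy",
                observed_value=go_acc,
                triggered=bool(go_acc < cfg.min_participant_go_accuracy),
            )
        )
        rows.append(
            dict(
                unit="participant", participant_id=pid, staircase_label=None,
                phase_index=None, block_index=None, rule="task_adherence",
                observed_value=stop_acc,
                triggered=bool(stop_acc < cfg.min_participant_stop_accuracy),
            )
        )
    return rows


def _block_rules(trials: pd.DataFrame, cfg: QCConfig) -> list[dict]:
    keys = ["participant_id", "staircase_label", "phase_index", "block_index"]
    rows = []
    for (pid, label, phase, block_ix), block in trials.groupby(keys, sort=True, observed=True):
        stop = block[block["trial_type"] == "stop"]
        stop_acc = float(stop["stop_success"].astype(bool).mean()) if len(stop) else np.nan
        slope = slowing_slope(block)
        base = dict(
            unit="block", participant_id=pid, staircase_label=label,
            phase_index=phase, block_index=block_ix,
        )
        rows.append(
            dict(base, rule="stop_accuracy", observed_value=stop_acc,
                 triggered=bool(stop_acc < cfg.min_block_stop_accuracy))
        )
        rows.append(
            dict(base, rule="slowing_slope", observed_value=slope,
                 triggered=bool(slope > cfg.max_slowing_slope_ms_per_go_trial + _BOUNDARY_TOL))
        )
    return rows


def _phase_rules(
    trials: pd.DataFrame,
    phase_ssrt: pd.DataFrame,
    cfg: QCConfig,
) -> list[dict]:
    keys = ["participant_id", "staircase_label", "phase_index"]
    ssrt_lookup = {
        (r.participant_id, r.staircase_label, r.phase_index): r.ssrt_ms
        for r in phase_ssrt.itertuples()
    }
    rows = []
    for (pid, label, phase), grp in trials.groupby(keys, sort=True, observed=True):
        go_rt = grp.loc[grp["trial_type"] == "go", "rt_ms"].dropna()
        sr_rt = grp.loc[
            (grp["trial_type"] == "stop") & grp["rt_ms"].notna(), "rt_ms"
        ]
        mean_go = float(go_rt.mean()) if len(go_rt) else np.nan
        mean_sr = float(sr_rt.mean()) if len(sr_rt) else np.nan
        # race-model check: go RTs must exceed signal-respond RTs on average
        race_violated = bool(len(sr_rt) and len(go_rt) and mean_go < mean_sr)
        base = dict(
            unit="phase", participant_id=pid, staircase_label=label,
            phase_index=phase, block_index=None,
        )
        rows.append(
            dict(base, rule="race_violation",
                 observed_value=mean_go - mean_sr if race_violated or len(sr_rt) else np.nan,
                 triggered=race_violated)
        )
        ssrt = ssrt_lookup.get((pid, label, phase), np.nan)
        rows.append(
            dict(base, rule="ssrt_floor", observed_value=ssrt,
                 triggered=bool(not np.isnan(ssrt) and ssrt < cfg.min_phase_ssrt_ms))
        )
    return rows


def apply_exclusions(
    trials: pd.DataFrame,
    block_estimates: pd.DataFrame,
    config: QCConfig = QCConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full exclusion pipeline.

    Returns ``(report, retained_blocks, retained_phases)``:

    * ``report`` — one row per unit x rule evaluated, with the observed
      value and whether it triggered;
    * ``retained_blocks`` — block estimates with a ``retained`` flag
      (participant-level exclusions cascade down);
    * ``retained_phases`` — phase-level SSRT after the one-block-excluded
      => phase-excluded rule and the phase rules.
    """
    report_rows = _participant_rules(trials, config)
    report_rows += _block_rules(trials, config)

    excluded_participants = {
        r["participant_id"] for r in report_rows
        if r["unit"] == "participant" and r["triggered"]
    }
    block_flags: dict[tuple, bool] = {}
    for r in report_rows:
        if r["unit"] != "block":
            continue
        key = (r["participant_id"], r["staircase_label"], r["phase_index"], r["block_index"])
        block_flags[key] = block_flags.get(key, False) or r["triggered"]
    for r in report_rows:
        if r["unit"] == "block" and r["triggered"]:
            logger.info(
                "QC: block excluded (%s=%.3g) participant=%s staircase=%s phase=%s block=%s",
                r["rule"], r["observed_value"], r["participant_id"],
                r["staircase_label"], r["phase_index"], r["block_index"],
            )

    blocks = block_estimates.copy()
    blocks["retained"] = [
        (r.participant_id not in excluded_participants)
        and not block_flags.get(
            (r.participant_id, r.staircase_label, r.phase_index, r.block_index), False
        )
        and bool(getattr(r, "estimable", True))
        for r in blocks.itertuples()
    ]

    phases = aggregate_phases(blocks, retained_col="retained")
    report_rows += _phase_rules(trials, phases, config)

    phase_flags = {
        (r["participant_id"], r["staircase_label"], r["phase_index"]): True
        for r in report_rows
        if r["unit"] == "phase" and r["triggered"]
    }
    phases["retained"] = [
        bool(r.retained)
        and (r.participant_id not in excluded_participants)
        and not phase_flags.get((r.participant_id, r.staircase_label, r.phase_index), False)
        for r in phases.itertuples()
    ]
    phases.loc[~phases["retained"], "ssrt_ms"] = np.nan

    report = pd.DataFrame(report_rows)
    return report, blocks, phases


def excluded_block_counts(report: pd.DataFrame, rule: str = "slowing_slope") -> pd.Series:
    """Number of blocks excluded under ``rule``, per staircase."""
    blk = report[(report["unit"] == "block") & (report["rule"] == rule) & report["triggered"]]
    return blk.groupby("staircase_label").size()


def exclusion_chisq(count_a: int, count_b: int) -> tuple[float, int]:
    """Pearson goodness-of-fit chi-square of two counts against an equal
    split; returns (statistic, df=1).

    E.g. 43 vs 19 excluded blocks gives chi2(1, N=62) = 9.29.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        raise ValueError("chi-square undefined for two zero counts")
    expected = total / 2.0
    stat = (count_a - expected) ** 2 / expected + (count_b - expected) ** 2 / expected
    return float(stat), 1
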