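"""Exclusion rules: slowing slopes, threshold semantics, chi-square."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stopsignal.qc import (
    QCConfig,
    apply_exclusions,
    excluded_block_counts,
    exclusion_chisq,
    slowing_slope,
)
from stopsignal.ssrt import estimate_blocks

from conftest import make_block


class TestSlowingSlope:
    def test_exact_linear_ramp(self):
        block = make_block(
            go_rts=[500 + 2 * i for i in range(10)],
            n_stop_respond=1, n_stop_success=1, ssds=[200.0, 200.0],
        )
        assert slowing_slope(block) == pytest.approx(2.0)

    def test_constant_rts_have_zero_slope(self):
        block = make_block(
            go_rts=[500] * 10, n_stop_respond=1, n_stop_success=1,
            ssds=[200.0, 200.0],
        )
        assert slowing_slope(block) == pytest.approx(0.0)

    def test_matches_closed_form_ols_oracle(self):
        """Sum((x-xbar)(y-ybar)) / Sum((x-xbar)^2) on {500,510,540}@{1,2,3}."""
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([500.0, 510.0, 540.0])
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        block = make_block(
            go_rts=y, n_stop_respond=1, n_stop_success=1, ssds=[200.0, 200.0]
        )
        assert oracle == pytest.approx(20.0)
        assert slowing_slope(block) == pytest.approx(oracle)

    def test_undefined_below_two_go_rts(self):
        block = make_block(
            go_rts=[500], n_stop_respond=1, n_stop_success=1, ssds=[200.0, 200.0]
        )
        assert np.isnan(slowing_slope(block))


def _blocks_with_slopes(slopes):
    """Noiseless blocks whose go RTs ramp at exactly the given slopes,
    one block per phase so the block rules are isolated."""
    frames = []
    for k, slope in enumerate(slopes, start=1):
        frames.append(
            make_block(
                go_rts=[500 + slope * i for i in range(20)],
                n_stop_respond=3, n_stop_success=3,
                ssds=[200.0] * 6, phase_index=k, block_index=1,
                signal_respond_rts=[430.0] * 3,
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestApplyExclusions:
    def test_strict_slope_threshold_excludes_only_above_two(self):
        trials = _blocks_with_slopes([0.0, 1.9, 2.0, 2.1])
        report, blocks, _ = apply_exclusions(trials, estimate_blocks(trials))
        slope_rows = report[(report["rule"] == "slowing_slope") & report["triggered"]]
        assert len(slope_rows) == 1
        assert slope_rows.iloc[0]["phase_index"] == 4
        assert blocks.loc[blocks["phase_index"] == 4, "retained"].eq(False).all()
        assert blocks.loc[blocks["phase_index"] != 4, "retained"].all()

    def test_low_stop_accuracy_excludes_block(self):
        trials = make_block(
            go_rts=[500] * 20, n_stop_respond=8, n_stop_success=2,
            ssds=[200.0] * 10, signal_respond_rts=[430.0] * 8,
        )
        report, _, _ = apply_exclusions(trials, estimate_blocks(trials))
        row = report[report["rule"] == "stop_accuracy"].iloc[0]
        assert row["observed_value"] == pytest.approx(0.2)
        assert row["triggered"]

    def test_boundary_stop_accuracy_retained(self):
        trials = make_block(
            go_rts=[500] * 20, n_stop_respond=6, n_stop_success=2,
            ssds=[200.0] * 8, signal_respond_rts=[430.0] * 6,
        )
        report, _, _ = apply_exclusions(trials, estimate_blocks(trials))
        row = report[report["rule"] == "stop_accuracy"].iloc[0]
        assert row["observed_value"] == pytest.approx(0.25)
        assert not row["triggered"]

    def test_race_violation_excludes_phase(self):
        # mean go RT 400 below mean signal-respond RT 420
        trials = make_block(
            go_rts=[400] * 20, n_stop_respond=4, n_stop_success=4,
            ssds=[200.0] * 8, signal_respond_rts=[420.0] * 4,
        )
        report, _, phases = apply_exclusions(trials, estimate_blocks(trials))
        row = report[report["rule"] == "race_violation"].iloc[0]
        assert row["triggered"]
        assert not phases["retained"].any()

    def test_ssrt_floor_excludes_phase(self):
        # go RTs near 250 with SSD 200 give an implausibly small SSRT
        trials = make_block(
            go_rts=[250 + i for i in range(20)], n_stop_respond=4,
            n_stop_success=4, ssds=[200.0] * 8,
            signal_respond_rts=[240.0] * 4,
        )
        report, _, phases = apply_exclusions(trials, estimate_blocks(trials))
        assert report[report["rule"] == "ssrt_floor"].iloc[0]["triggered"]
        assert not phases["retained"].any()

    def test_low_go_accuracy_excludes_participant(self):
        trials = make_block(
            go_rts=[500] * 20, n_stop_respond=4, n_stop_success=4,
            ssds=[200.0] * 8, signal_respond_rts=[430.0] * 4,
        )
        # flip most go responses to the wrong key
        go_idx = trials.index[trials["trial_type"] == "go"][:15]
        trials.loc[go_idx, "response"] = "right"
        report, blocks, _ = apply_exclusions(trials, estimate_blocks(trials))
        row = report[report["rule"] == "go_accuracy"].iloc[0]
        assert row["observed_value"] == pytest.approx(0.25)
        assert row["triggered"]
        assert not blocks["retained"].any()

    def test_tightening_threshold_is_monotone(self, small_cohort_frame):
        """No unit excluded at the default slope threshold is retained at
        a stricter one."""
        blocks = estimate_blocks(small_cohort_frame)
        _, loose, _ = apply_exclusions(small_cohort_frame, blocks, QCConfig())
        _, tight, _ = apply_exclusions(
            small_cohort_frame, blocks,
            QCConfig(max_slowing_slope_ms_per_go_trial=1.0),
        )
        merged = loose.merge(
            tight,
            on=["participant_id", "staircase_label", "phase_index", "block_index"],
            suffixes=("_loose", "_tight"),
        )
        assert not (merged["retained_tight"] & ~merged["retained_loose"]).any()


class TestExclusionChisq:
    def test_printed_counts(self):
        stat, df = exclusion_chisq(43, 19)
        assert df == 1
        assert stat == pytest.approx(9.29, abs=0.005)

    def test_equal_split_is_zero(self):
        assert exclusion_chisq(31, 31)[0] == 0.0

    def test_closed_form_oracle(self):
        stat, _ = exclusion_chisq(10, 20)
        assert stat == pytest.approx(10.0 / 3)

    def test_matches_scipy_pearson_statistic(self):
        for a, b in [(43, 19), (10, 20), (5, 5), (1, 12)]:
            stat, _ = exclusion_chisq(a, b)
            assert stat == pytest.approx(stats.chisquare([a, b]).statistic)

    def test_two_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            exclusion_chisq(0, 0)


def test_excluded_block_counts_by_staircase():
    trials = pd.concat(
        [
            _blocks_with_slopes([2.5, 0.0]),
            _blocks_with_slopes([3.0, 2.2]).assign(staircase_label="p66"),
        ],
        ignore_index=True,
    )
    report, _, _ = apply_exclusions(trials, estimate_blocks(trials))
    counts = excluded_block_counts(report)
    assert counts.to_dict() == {"p50": 1, "p66": 2}
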