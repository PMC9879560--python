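"""Descriptive and reliability statistics for SSRT estimates.

Within-experiment test-retest reliability correlates the two phases run
under the same staircase across participants; the cross-staircase
correlation relates each participant's staircase-level means.  Pearson r
is computed over pairwise-complete participants with a two-sided p-value
from the t transform.  Descriptive tables report n, missing, mean, sample
SD (n-1 denominator), minimum and maximum per condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ReliabilityReport", "test_retest", "pairwise_pearson", "descriptives"]

PAIRINGS = ("phase1_vs_phase2_p50", "phase1_vs_phase2_p66", "p50_vs_p66_means")


@dataclass(frozen=True)
class ReliabilityReport:
    pairing: str
    grouping: str           # "overall" or an environment name
    n_pairs: int
    pearson_r: Optional[float]
    p_value: Optional[float]


def pairwise_pearson(x: pd.Series, y: pd.Series) -> tuple[int, Optional[float], Optional[float]]:
    """Pearson r over pairwise-complete observations; undefined below n=3."""
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    if n < 3:
        return n, None, None
    r, p = stats.pearsonr(x[ok], y[ok])
    return n, float(r), float(p)


def _phase_occurrence(phase_estimates: pd.DataFrame) -> pd.DataFrame:
    """Label each phase as the 1st or 2nd occurrence of its staircase."""
    df = phase_estimates.sort_values(
        ["participant_id", "staircase_label", "phase_index"]
    ).copy()
    df["occurrence"] = df.groupby(["participant_id", "staircase_label"]).cumcount() + 1
    return df


def test_retest(
    phase_estimates: pd.DataFrame,
    pairing: str,
    grouping: Optional[str] = None,
) -> ReliabilityReport:
    """Reliability correlation for one pairing.

    ``phase_estimates`` must carry phase-level ``ssrt_ms`` (excluded
    phases as NaN) with ``participant_id``, ``staircase_label``,
    ``phase_index`` and ``environment`` columns.  ``grouping`` restricts
    to one testing environment.
    """
    if pairing not in PAIRINGS:
        raise ValueError(f"unknown pairing {pairing!r}; choose from {PAIRINGS}")
    df = phase_estimates
    if grouping is not None:
        df = df[df["environment"] == grouping]

    if pairing == "p50_vs_p66_means":
        means = df.groupby(["participant_id", "staircase_label"], observed=True)[
            "ssrt_ms"
        ].mean().unstack("staircase_label")
        x, y = means.get("p50"), means.get("p66")
    else:
        label = "p50" if pairing.endswith("p50") else "p66"
        occ = _phase_occurrence(df[df["staircase_label"] == label])
        wide = occ.pivot_table(
            index="participant_id", columns="occurrence", values="ssrt_ms"
        )
        x, y = wide.get(1), wide.get(2)

    if x is None or y is None:
        return ReliabilityReport(pairing, grouping or "overall", 0, None, None)
    n, r, p = pairwise_pearson(x, y)
    return ReliabilityReport(pairing, grouping or "overall", n, r, p)


def descriptives(
    estimates: pd.DataFrame,
    value_col: str = "ssrt_ms",
    groupby: list[str] | str = "staircase_label",
) -> pd.DataFrame:
    """Per-condition n, missing, mean, SD, min, max of an estimate column.

    ``n`` counts non-missing values; sample SD uses the n-1 denominator
    and is reported as missing at n=1.
    """
    if isinstance(groupby, str):
        groupby = [groupby]
    rows = []
    for keys, grp in estimates.groupby(groupby, sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = grp[value_col].dropna()
        rows.append(
            dict(zip(groupby, keys))
            | {
                "n": int(len(vals)),
                "missing": int(grp[value_col].isna().sum()),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "min": float(vals.min()) if len(vals) else np.nan,
                "max": float(vals.max()) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows)
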