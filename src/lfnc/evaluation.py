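"""Bias of the closed-form estimators against the simulated effective FiO2.

Differences are signed (formula minus simulated, percentage points):
negative means the formula underestimates oxygen delivery.  Replicate-
averaged values feed the difference computation; replicate-level triplets
feed the Mann-Whitney rank-sum tests.  Threshold summaries report, per flow,
the smallest minute ventilation above which the mean bias stays below a
clinical threshold (3 or 5 pp).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from lfnc.formulas import benaron_benitz_fio2, finer_fio2

#: combined sample size at or below which the rank-sum p-value is exact
EXACT_ENUMERATION_LIMIT = 12

FORMULAS = ("benaron_benitz", "finer")


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U (midrank-tied) with a two-sided p-value."""

    u_statistic: float
    p_value: float
    n1: int
    n2: int


def formula_differences(
    dataset: pd.DataFrame,
    formula_name: str,
    supply_o2_percent: float = 100.0,
) -> pd.DataFrame:
    """Per-cell signed bias of a formula against the simulated FiO2.

    ``dataset`` is the simulated-protocol frame (one row per replicate);
    cells are replicate-averaged before differencing.  Returns columns
    mv_ml_min, flow_l_min, formula_name, diff_pp.
    """
    if formula_name not in FORMULAS:
        raise ValueError(f"unknown formula {formula_name!r}; expected one of {FORMULAS}")
    cells = dataset.groupby(
        ["vt_ml", "rr_bpm", "ti_ms", "flow_l_min"], as_index=False
    ).agg(mv_ml_min=("mv_ml_min", "first"), fio2_percent=("fio2_percent", "mean"))

    if formula_name == "benaron_benitz":
        pred = [
            benaron_benitz_fio2(r.flow_l_min, r.ti_ms, r.vt_ml, supply_o2_percent).fio2_percent
            for r in cells.itertuples()
        ]
    else:
        pred = [
            finer_fio2(r.flow_l_min, r.mv_ml_min, supply_o2_percent).fio2_percent
            for r in cells.itertuples()
        ]
    out = cells[["mv_ml_min", "flow_l_min"]].copy()
    out["formula_name"] = formula_name
    out["diff_pp"] = np.asarray(pred) - cells["fio2_percent"].to_numpy()
    return out


def _u_from_pairs(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x by direct pairwise counting (wins + half-ties)."""
    gt = np.sum(x[:, None] > y[None, :])
    eq = np.sum(x[:, None] == y[None, :])
    return float(gt + 0.5 * eq)


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    The p-value is exact (full enumeration of rank assignments) when
    n1 + n2 <= 12, otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    u = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        mu = n1 * n2 / 2.0
        obs_dev = abs(u - mu)
        total = math.comb(n1 + n2, n1)
        hits = 0
        rank_sum_offset = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u_perm = ranks[list(combo)].sum() - rank_sum_offset
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        p = float(
            mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    return RankSumResult(u_statistic=u, p_value=min(p, 1.0), n1=n1, n2=n2)


def bias_threshold_summary(
    records: pd.DataFrame,
    thresholds_pp: Sequence[float] = (3.0, 5.0),
    mv_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Smallest MV above which |mean bias| stays within each threshold, per flow.

    For each cannula flow and threshold, scans the MV grid in increasing
    order and reports the smallest grid value m such that every MV bin from
    m upward has |mean diff| within the threshold; ``min_mv_ml_min`` is NaN
    when no grid value qualifies (bias beyond threshold at all MVs).
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    rows = []
    for (flow, formula), grp in records.groupby(["flow_l_min", "formula_name"]):
        binned = grp.groupby("mv_ml_min")["diff_pp"].mean()
        grid = sorted(mv_grid) if mv_grid is not None else sorted(binned.index)
        for thr in thresholds_pp:
            found = np.nan
            for m in grid:
                above = binned[binned.index >= m]
                if (above.abs() <= thr).all():
                    found = m
                    break
            rows.append(
                {
                    "flow_l_min": flow,
                    "formula_name": formula,
                    "threshold_pp": thr,
                    "min_mv_ml_min": found,
                }
            )
    return pd.DataFrame(
        rows, columns=["flow_l_min", "formula_name", "threshold_pp", "min_mv_ml_min"]
    )
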