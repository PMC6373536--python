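"""Trial exclusion rules and per-cell summary statistics.

Pipeline order is fixed: participants with an error rate over the
threshold are excluded first (on unfiltered main-block trials), then the
RT window is applied, then trials are reduced to per-participant design
cells. Practice trials never enter any analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CELL_COLUMNS

__all__ = ["main_trials", "filter_rts", "exclude_participants", "summarize_cells"]

CELL_FACTORS = ("expression", "required_response", "face_gender")


def main_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop practice trials."""
    return trials[trials["block"] != "practice"]


def filter_rts(
    trials: pd.DataFrame, lo_ms: float = 200.0, hi_ms: float = 2500.0
) -> tuple[pd.DataFrame, float]:
    """Remove trials with RT strictly below ``lo_ms`` or above ``hi_ms``.

    Returns the kept trials and the removed proportion over main-block
    trials (0.0 for empty input). RTs exactly at a bound are kept.
    """
    if trials.empty:
        return trials, 0.0
    rt = trials["rt_ms"]
    keep = (rt >= lo_ms) & (rt <= hi_ms)
    main = main_trials(trials)
    n_main = len(main)
    removed_main = int((~keep.loc[main.index]).sum()) if n_main else 0
    return trials[keep], (removed_main / n_main if n_main else 0.0)


def exclude_participants(
    trials: pd.DataFrame, error_threshold: float = 0.45
) -> tuple[pd.DataFrame, list[str]]:
    """Drop participants whose main-block error rate exceeds the threshold.

    The bound is strict: a participant at exactly the threshold is kept.
    """
    main = main_trials(trials)
    err = 1.0 - main.groupby("participant_id")["correct"].mean()
    excluded = sorted(err.index[err > error_threshold])
    return trials[~trials["participant_id"].isin(excluded)], excluded


def summarize_cells(
    trials: pd.DataFrame, factors: tuple[str, ...] = CELL_FACTORS
) -> pd.DataFrame:
    """Per-participant, per-cell response summaries feeding the EZ estimator.

    ``factors`` selects the design cells (subset of expression,
    required_response, face_gender); omitted factors are pooled over and
    reported as ``"pooled"``. Mean and variance (n-1 denominator) are of
    correct-response RTs in seconds; the median is kept in ms. A cell with
    fewer than two correct trials, or proportion correct exactly 0, 0.5 or
    1, is flagged degenerate (edge correction happens downstream).
    """
    unknown = set(factors) - set(CELL_FACTORS)
    if unknown:
        raise ValueError(f"unknown cell factors: {sorted(unknown)}")
    main = main_trials(trials)
    keys = ["participant_id", "participant_gender", *factors]
    rows = []
    for key, cell in main.groupby(keys, sort=True):
        key = dict(zip(keys, key))
        correct_rts = cell.loc[cell["correct"], "rt_ms"].to_numpy(dtype=float)
        n_total, n_correct = len(cell), len(correct_rts)
        pc = n_correct / n_total
        degenerate = n_correct < 2 or pc in (0.0, 0.5, 1.0)
        rows.append(
            {
                **key,
                **{f: "pooled" for f in CELL_FACTORS if f not in factors},
                "n_total": n_total,
                "n_correct": n_correct,
                "pc": pc,
                "mrt_s": correct_rts.mean() / 1000.0 if n_correct else np.nan,
                "vrt_s2": (
                    correct_rts.var(ddof=1) / 1e6 if n_correct >= 2 else np.nan
                ),
                "median_rt_ms": (
                    float(np.median(correct_rts)) if n_correct else np.nan
                ),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)
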