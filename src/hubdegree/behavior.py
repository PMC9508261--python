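"""Behavioral outcome assembly and group comparisons.

Combines load-wise working-memory performance (accuracy and reaction time
at loads 1/3/5/7) into the summary outcomes used by the degree analysis and
produces the group-comparison table (means, SDs, two-sample t-tests per
load and combined).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import ttest_two_sample

logger = logging.getLogger(__name__)

WM_LOADS = (1, 3, 5, 7)

__all__ = ["WM_LOADS", "combine_outcomes", "group_compare"]


def combine_outcomes(
    accuracy: Mapping[int, float],
    reaction_time: Mapping[int, float],
    trial_counts: Mapping[int, int] | None = None,
    loads: Sequence[int] = WM_LOADS,
) -> tuple[float, float]:
    """Combined accuracy and reaction time across WM loads.

    Combined accuracy is the unweighted mean over loads.  Combined RT is
    the trial-count-weighted mean when trial counts are given (averaging
    across all trials), otherwise the plain mean over loads.
    """
    loads = tuple(loads)
    if not loads:
        raise ValueError("at least one load must be declared")
    unknown = set(loads) - set(WM_LOADS)
    if unknown:
        raise ValueError(f"unknown WM loads {sorted(unknown)}; valid: {WM_LOADS}")
    missing = [l for l in loads if l not in accuracy or l not in reaction_time]
    if missing:
        raise ValueError(f"loads {missing} missing from the performance record")
    acc = float(np.mean([accuracy[l] for l in loads]))
    rts = np.array([reaction_time[l] for l in loads], dtype=float)
    if trial_counts is not None:
        w = np.array([trial_counts[l] for l in loads], dtype=float)
        rt = float(np.average(rts, weights=w))
    else:
        rt = float(rts.mean())
    return acc, rt


def group_compare(
    records: pd.DataFrame,
    outcome: str = "acc",
    variant: str = "pooled",
    loads: Sequence[int] = WM_LOADS,
) -> pd.DataFrame:
    """Two-sample group comparison per WM load and combined.

    ``records`` needs a ``group`` column with two levels and columns
    ``{outcome}_{load}`` plus ``{outcome}_combined``.  Rows with missing
    values are excluded listwise per column with a logged count.  Per-load
    p-values are reported uncorrected.
    """
    groups = pd.unique(records["group"])
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    ga, gb = groups
    rows = []
    for label in [*(f"{outcome}_{l}" for l in loads), f"{outcome}_combined"]:
        col = records[label]
        n_missing = int(col.isna().sum())
        if n_missing:
            logger.warning("%s: %d missing value(s) excluded", label, n_missing)
        a = col[(records["group"] == ga) & col.notna()].to_numpy(float)
        b = col[(records["group"] == gb) & col.notna()].to_numpy(float)
        res = ttest_two_sample(a, b, variant=variant)
        rows.append(
            {
                "measure": label,
                f"mean_{ga}": a.mean(),
                f"sd_{ga}": a.std(ddof=1),
                f"n_{ga}": a.size,
                f"mean_{gb}": b.mean(),
                f"sd_{gb}": b.std(ddof=1),
                f"n_{gb}": b.size,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows).set_index("measure")
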