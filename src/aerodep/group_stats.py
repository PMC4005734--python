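"""Bonferroni pairwise multiple-comparison analysis of grouped measurements.

Groups are aerosol size classes; values are per-inhalation regional
deposition measures.  Default test is the unpaired two-sided Welch t with
Bonferroni adjustment (p multiplied by the number of pairs, clamped at 1);
a paired mode (by-subject pairing) is available since small crossover
designs — every subject inhaling every aerosol — are usually analysed
paired.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["bonferroni_pairwise", "summarize_groups"]

GroupedMeasurements = Mapping[str, Sequence[float]]


def _validate(data: GroupedMeasurements) -> dict[str, np.ndarray]:
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for label, values in data.items():
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 values")
        out[label] = v
    return out


def bonferroni_pairwise(
    data: GroupedMeasurements,
    alpha: float = 0.05,
    paired: bool = False,
    equal_var: bool = False,
) -> pd.DataFrame:
    """All pairwise two-sided t tests with Bonferroni adjustment.

    Parameters
    ----------
    data : mapping of group label -> per-inhalation values
    alpha : family-wise significance level applied to the adjusted p.
    paired : use the paired t test (groups must then be equal-length with
        matching order, e.g. sorted by subject and replicate).
    equal_var : pooled-variance t instead of Welch (unpaired mode only).

    Returns
    -------
    DataFrame with one row per pair: group labels, means, raw p, Bonferroni-
    adjusted p (raw x number of pairs, clamped at 1), significance flag.
    Degenerate pairs (both groups constant and identical) get p = 1.
    """
    groups = _validate(data)
    pairs = list(combinations(groups, 2))
    k = len(pairs)
    rows = []
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
            raw_p = 1.0  # no variance, no difference: nothing to test
        elif paired:
            if va.size != vb.size:
                raise ValueError(
                    f"paired test needs equal group sizes ({a}: {va.size}, "
                    f"{b}: {vb.size})"
                )
            raw_p = float(stats.ttest_rel(va, vb).pvalue)
        else:
            raw_p = float(stats.ttest_ind(va, vb, equal_var=equal_var).pvalue)
        adj_p = min(1.0, raw_p * k)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": float(va.mean()),
                "mean_b": float(vb.mean()),
                "raw_p": raw_p,
                "adjusted_p": adj_p,
                "significant": adj_p < alpha,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(data: GroupedMeasurements) -> pd.DataFrame:
    """Sample mean, SD (n-1 denominator) and n per group.

    SD is reported as NaN for singleton groups (validation requires n >= 2,
    so this only arises via direct construction).
    """
    groups = _validate(data)
    rows = [
        {
            "group": label,
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        }
        for label, v in groups.items()
    ]
    return pd.DataFrame(rows).set_index("group")
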