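"""Covariate balance diagnostics before and after matching.

The balance statistic is the normalized difference
``(mean_t - mean_c) / sqrt((var_t + var_c) / 2)``; values with absolute
magnitude above 0.25 flag a covariate as imbalanced. For a matched sample
the control moments are weighted by the control reuse counts, matching the
semantics of nearest-neighbor matching with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

IMBALANCE_THRESHOLD = 0.25


@dataclass
class BalanceRow:
    covariate: str
    treated_mean: float
    control_mean: float
    treated_sd: float
    control_sd: float
    normalized_difference: float
    flag: str  # "ok" | "imbalanced"


def _weighted_moments(x: np.ndarray, w: Optional[np.ndarray]):
    """Mean and unbiased variance, with frequency (reuse-count) weights."""
    if w is None:
        mean = float(np.mean(x))
        var = float(np.var(x, ddof=1)) if x.size > 1 else 0.0
        return mean, var
    w = np.asarray(w, dtype=float)
    n = w.sum()
    mean = float(np.sum(w * x) / n)
    if n > 1:
        var = float(np.sum(w * (x - mean) ** 2) / (n - 1))
    else:
        var = 0.0
    return mean, var


def normalized_difference(x_treated: Sequence[float],
                          x_control: Sequence[float],
                          weights: Optional[Sequence[float]] = None) -> float:
    """Normalized mean difference between treated and control samples.

    ``weights`` (optional, non-negative) are frequency weights on the
    control sample, e.g. matched-control reuse counts. Zero pooled variance
    with unequal means returns signed infinity (flagged imbalanced
    downstream); zero variance with equal means returns 0.
    """
    x_t = np.asarray(x_treated, dtype=float)
    x_c = np.asarray(x_control, dtype=float)
    if x_t.size < 2 or x_c.size < 2:
        raise ValueError("need at least 2 values per group")
    if weights is not None and np.any(np.asarray(weights, dtype=float) < 0):
        raise ValueError("weights must be non-negative")
    mean_t, var_t = _weighted_moments(x_t, None)
    mean_c, var_c = _weighted_moments(x_c, weights)
    pooled = (var_t + var_c) / 2.0
    diff = mean_t - mean_c
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        return math.copysign(math.inf, diff)
    return diff / math.sqrt(pooled)


def balance_table(sample: pd.DataFrame,
                  treated_mask: np.ndarray,
                  covariates: Sequence[str],
                  matched=None,
                  threshold: float = IMBALANCE_THRESHOLD) -> List[BalanceRow]:
    """One :class:`BalanceRow` per covariate.

    With ``matched=None`` the table compares raw treated vs. raw control
    units. With a matched sample (``tenurematch.matchcore.MatchedSample``)
    the treated side is the matched treated units and the control side the
    distinct matched controls weighted by reuse counts.
    """
    treated_mask = np.asarray(treated_mask, dtype=bool)
    rows: List[BalanceRow] = []
    if matched is None:
        t_df = sample.loc[treated_mask]
        c_df = sample.loc[~treated_mask]
        weights = None
    else:
        t_df = sample.loc[matched.treated_ids]
        c_ids, counts = np.unique(matched.control_ids, return_counts=True)
        c_df = sample.loc[c_ids]
        weights = counts.astype(float)

    for cov in covariates:
        x_t = t_df[cov].to_numpy(dtype=float)
        x_c = c_df[cov].to_numpy(dtype=float)
        nd = normalized_difference(x_t, x_c, weights)
        mean_t, var_t = _weighted_moments(x_t, None)
        mean_c, var_c = _weighted_moments(x_c, weights)
        rows.append(BalanceRow(
            covariate=cov,
            treated_mean=mean_t,
            control_mean=mean_c,
            treated_sd=math.sqrt(var_t),
            control_sd=math.sqrt(var_c),
            normalized_difference=nd,
            flag="imbalanced" if abs(nd) > threshold else "ok",
        ))
    return rows


def max_abs_nd(rows: Sequence[BalanceRow]) -> float:
    return max(abs(r.normalized_difference) for r in rows)


def mean_abs_nd(rows: Sequence[BalanceRow]) -> float:
    return float(np.mean([abs(r.normalized_difference) for r in rows]))


def balance_frame(rows: Sequence[BalanceRow]) -> pd.DataFrame:
    """Balance rows as a DataFrame for CSV export."""
    return pd.DataFrame([r.__dict__ for r in rows])
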