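"""Treatment-assignment (propensity) model and common-support trimming.

The propensity score is the fitted probability from an unregularized
maximum-likelihood logit of the binary treatment on the matching
covariates; the linearized score is its log-odds transform
``l = log(p / (1 - p))``. Trimming removes treated units outside the
control score range (min-max common support), plus optionally treated
units with no control within a caliper on the linearized score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


class SeparationError(RuntimeError):
    """The logit is (quasi-)separated or failed to converge."""


class TrimmingError(RuntimeError):
    """Common-support trimming removed every treated unit."""


@dataclass
class PropensityFit:
    label: str
    covariates: list
    params: pd.Series          # intercept ("const") + slopes
    bse: pd.Series
    phat: pd.Series            # per-unit fitted probability, index = unit id
    lps: pd.Series             # linearized propensity score log(p/(1-p))
    converged: bool


def fit_propensity(sample: pd.DataFrame, treated: np.ndarray,
                   covariate_names: Sequence[str],
                   label: str = "treatment") -> PropensityFit:
    """Maximum-likelihood logit of *treated* on the named covariates.

    Raises :class:`SeparationError` on perfect separation or
    non-convergence (the caller may drop offending covariates and retry).
    """
    treated = np.asarray(treated, dtype=float)
    if treated.sum() == 0 or treated.sum() == len(treated):
        raise ValueError("both treatment arms must be non-empty")
    X = sm.add_constant(sample[list(covariate_names)].astype(float),
                        has_constant="add")
    if X.isna().any().any():
        raise ValueError("covariates contain missing values")
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    model = sm.Logit(treated, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = model.fit(disp=False, maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise SeparationError(f"logit fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logit did not converge (possible separation)")
    phat = pd.Series(np.asarray(res.predict(X)), index=sample.index)
    eps = 1e-12
    phat_c = phat.clip(eps, 1 - eps)
    lps = np.log(phat_c / (1 - phat_c))
    if not np.all(np.isfinite(lps)):
        raise SeparationError("non-finite linearized scores")
    return PropensityFit(
        label=label,
        covariates=list(covariate_names),
        params=res.params,
        bse=res.bse,
        phat=phat_c,
        lps=lps,
        converged=bool(res.mle_retvals.get("converged", False)),
    )


def trim_common_support(sample: pd.DataFrame, treated: np.ndarray,
                        fit: PropensityFit, caliper_sd: float = 0.25):
    """Drop treated units off the control linearized-score support.

    A treated unit is dropped if its score lies outside the [min, max] of
    the control scores, or (``caliper_sd > 0``) if no control score lies
    within ``caliper_sd x SD(l)`` of it. Controls are never removed.

    Returns ``(on_support_mask, n_trimmed)`` where the mask is aligned with
    ``sample`` and keeps all controls.
    """
    treated = np.asarray(treated, dtype=bool)
    lps = fit.lps.loc[sample.index].to_numpy()
    lc = lps[~treated]
    lt = lps[treated]
    lo, hi = lc.min(), lc.max()
    keep_t = (lt >= lo) & (lt <= hi)
    if caliper_sd > 0:
        sd = lps.std(ddof=1)
        caliper = caliper_sd * sd
        lc_sorted = np.sort(lc)
        idx = np.searchsorted(lc_sorted, lt)
        left = np.where(idx > 0, np.abs(lt - lc_sorted[np.maximum(idx - 1, 0)]),
                        np.inf)
        right = np.where(idx < lc_sorted.size,
                         np.abs(lc_sorted[np.minimum(idx, lc_sorted.size - 1)] - lt),
                         np.inf)
        keep_t &= np.minimum(left, right) <= caliper
    mask = np.ones(len(sample), dtype=bool)
    t_idx = np.flatnonzero(treated)
    mask[t_idx[~keep_t]] = False
    n_trimmed = int((~keep_t).sum())
    if keep_t.sum() == 0:
        raise TrimmingError("all treated units trimmed off common support")
    return mask, n_trimmed


def propensity_frame(fit: PropensityFit) -> pd.DataFrame:
    """Coefficient summary (covariate, coefficient, se) for CSV export."""
    return pd.DataFrame({
        "covariate": fit.params.index,
        "coefficient": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
    })
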