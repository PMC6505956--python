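"""Nearest-neighbor matching with replacement and ATT estimation.

Treated pixels are matched (within forest biome) to their closest control
pixel under a Mahalanobis metric — optionally augmented with the
linearized propensity score as an extra standardized coordinate — subject
to the constraint that a control never comes from the treated pixel's own
cadastral property. The estimand is the average treatment effect on the
treated (ATT): the mean over matched pairs of
``tt_i = Y_treated - Y_control``, where Y is the binary forest-loss
outcome. A negative ATT means the treatment reduced the probability of
forest loss.

Post-matching adjustments follow the standard regression bias correction
(a linear outcome model fit on the matched controls absorbs residual
covariate gaps within pairs) and matched-sample variance estimators that
account for control reuse, with an optional nearest-neighbor
heteroscedasticity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from . import balance as balance_mod
from . import propensity as propensity_mod
from .schema import COVARIATES

METRICS = ("mahalanobis_trimmed", "ps_augmented")

CI_LEVELS = (90, 95, 99)

#: Comparisons with fewer treated units than this are reported NA
#: ("very small treated pool") rather than estimated.
MIN_TREATED = 25


class MatchingInfeasibleError(RuntimeError):
    """No candidate matching estimator produced a feasible matched sample."""


# ---------------------------------------------------------------------------
# Distance machinery
# ---------------------------------------------------------------------------

def pooled_inverse_covariance(X: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Inverse of the pooled covariance of the stacked matching matrix.

    Near-singular covariances are regularized by adding
    ``ridge x trace(S)`` to the diagonal before inversion.
    """
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    tr = np.trace(S)
    if tr <= 0:
        tr = 1.0
    S_reg = S + ridge * tr * np.eye(S.shape[0])
    try:
        return np.linalg.inv(S_reg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular covariance even after regularization: {exc}")


def mahalanobis_distance(u: np.ndarray, v: np.ndarray,
                         inverse_covariance: np.ndarray) -> float:
    """``sqrt((u - v)' S^-1 (u - v))``; zero iff u == v."""
    d = np.asarray(u, dtype=float) - np.asarray(v, dtype=float)
    q = float(d @ inverse_covariance @ d)
    return float(np.sqrt(max(q, 0.0)))


def _whiten(X: np.ndarray, inverse_covariance: np.ndarray) -> np.ndarray:
    """Linear map such that Euclidean distance equals Mahalanobis distance."""
    L = np.linalg.cholesky(inverse_covariance)
    return X @ L


def _matching_matrix(sample: pd.DataFrame, covariates: Sequence[str],
                     metric: str, lps: Optional[pd.Series]) -> np.ndarray:
    X = sample[list(covariates)].to_numpy(dtype=float)
    if metric == "ps_augmented":
        if lps is None:
            raise ValueError("ps_augmented metric requires linearized scores")
        ell = lps.loc[sample.index].to_numpy(dtype=float)
        sd = ell.std(ddof=1)
        if sd == 0:
            sd = 1.0
        X = np.column_stack([X, (ell - ell.mean()) / sd])
    elif metric != "mahalanobis_trimmed":
        raise ValueError(f"unknown metric: {metric}")
    return X


# ---------------------------------------------------------------------------
# Matched sample
# ---------------------------------------------------------------------------

@dataclass
class MatchedSample:
    """Treated/control pair set from nearest-neighbor matching."""

    treated_ids: np.ndarray       # index labels into the pixel table
    control_ids: np.ndarray
    distances: np.ndarray
    tt: np.ndarray                # per-pair effect Y_treated - Y_control
    metric: str
    stratum: str
    n_dropped: int = 0            # treated with no admissible control

    def __len__(self) -> int:
        return len(self.treated_ids)

    @property
    def reuse_counts(self) -> pd.Series:
        """Times each distinct control is used; sums to the pair count."""
        ids, counts = np.unique(self.control_ids, return_counts=True)
        return pd.Series(counts, index=ids)

    @property
    def n_matched_controls(self) -> int:
        return int(np.unique(self.control_ids).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "treated_id": self.treated_ids,
            "control_id": self.control_ids,
            "distance": self.distances,
            "tt": self.tt,
        })


def match_nearest_neighbor(sample: pd.DataFrame, treated_mask: np.ndarray,
                           covariates: Sequence[str] = COVARIATES,
                           metric: str = "mahalanobis_trimmed",
                           lps: Optional[pd.Series] = None,
                           same_biome: bool = True,
                           different_property: bool = True,
                           k: int = 1,
                           stratum: str = "",
                           chunk: int = 256) -> MatchedSample:
    """Match each treated unit to its ``k`` nearest admissible controls.

    Matching is with replacement; distance ties are broken by the lowest
    control id so reruns are deterministic. A treated unit with no
    admissible control is dropped (counted in ``n_dropped``). With
    ``k > 1``, ``tt_i`` uses the mean outcome of the k controls and one
    pair row is emitted per (treated, control).
    """
    treated_mask = np.asarray(treated_mask, dtype=bool)
    if len(treated_mask) != len(sample):
        raise ValueError("treated_mask must align with sample")
    # sort by id so argmin tie-breaks resolve to the lowest control id
    treated_ser = pd.Series(treated_mask, index=sample.index)
    sample = sample.sort_index()
    treated_ser = treated_ser.loc[sample.index]
    strata = (sample["biome"].unique() if same_biome and "biome" in sample
              else ["all"])

    t_ids_all, c_ids_all, d_all, tt_all = [], [], [], []
    n_dropped = 0

    for b in strata:
        sub = sample if b == "all" else sample[sample["biome"] == b]
        t_sub = sub[treated_ser.loc[sub.index].to_numpy()]
        c_sub = sub[~treated_ser.loc[sub.index].to_numpy()]
        if len(t_sub) == 0:
            continue
        if len(c_sub) == 0:
            n_dropped += len(t_sub)
            continue
        pool = pd.concat([t_sub, c_sub])
        Xp = _matching_matrix(pool, covariates, metric, lps)
        VI = pooled_inverse_covariance(Xp)
        W = _whiten(Xp, VI)
        Wt, Wc = W[: len(t_sub)], W[len(t_sub):]
        y_c = c_sub["y_loss"].to_numpy(dtype=float)
        y_t = t_sub["y_loss"].to_numpy(dtype=float)
        c_prop = (c_sub["property_id"].to_numpy()
                  if different_property and "property_id" in c_sub else None)
        t_prop = (t_sub["property_id"].to_numpy()
                  if c_prop is not None else None)
        c_index = c_sub.index.to_numpy()
        t_index = t_sub.index.to_numpy()

        for start in range(0, len(t_sub), chunk):
            stop = min(start + chunk, len(t_sub))
            D = cdist(Wt[start:stop], Wc)
            if c_prop is not None:
                same = t_prop[start:stop, None] == c_prop[None, :]
                D[same] = np.inf
            if k == 1:
                j = np.argmin(D, axis=1)  # first min -> lowest control id
                dmin = D[np.arange(len(j)), j]
                ok = np.isfinite(dmin)
                n_dropped += int((~ok).sum())
                t_ids_all.append(t_index[start:stop][ok])
                c_ids_all.append(c_index[j[ok]])
                d_all.append(dmin[ok])
                tt_all.append(y_t[start:stop][ok] - y_c[j[ok]])
            else:
                order = np.argsort(D, axis=1, kind="stable")
                for r in range(stop - start):
                    js = order[r][np.isfinite(D[r][order[r]])][:k]
                    if js.size < k:
                        n_dropped += 1
                        continue
                    tt_val = y_t[start + r] - y_c[js].mean()
                    for j1 in js:
                        t_ids_all.append([t_index[start + r]])
                        c_ids_all.append([c_index[j1]])
                        d_all.append([D[r, j1]])
                        tt_all.append([tt_val])

    if not t_ids_all:
        return MatchedSample(np.array([]), np.array([]), np.array([]),
                             np.array([]), metric, stratum, n_dropped)
    return MatchedSample(
        treated_ids=np.concatenate(t_ids_all),
        control_ids=np.concatenate(c_ids_all),
        distances=np.concatenate(d_all).astype(float),
        tt=np.concatenate(tt_all).astype(float),
        metric=metric,
        stratum=stratum,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# ATT, bias adjustment, variance
# ---------------------------------------------------------------------------

def raw_att(m: MatchedSample) -> float:
    """Mean over pairs of ``tt_i``."""
    if len(m) == 0:
        raise ValueError("matched sample is empty")
    return float(np.mean(m.tt))


def bias_adjust(m: MatchedSample, sample: pd.DataFrame,
                adjustment_covariates: Sequence[str] = COVARIATES,
                ) -> Tuple[float, np.ndarray]:
    """Regression bias correction of the matched-pair effects.

    A linear outcome model ``Y ~ x`` is fit on the matched controls
    (frequency-weighted by reuse counts); the predicted outcome gap
    ``mu(x_treated) - mu(x_control)`` is subtracted from each ``tt_i``.
    Returns ``(adjusted ATT, adjusted tt vector)``. Collinear columns are
    handled by a minimum-norm least-squares fit (with a warning), which is
    equivalent to dropping redundant directions.
    """
    cols = list(adjustment_covariates)
    if len(m) < len(cols) + 2:
        raise ValueError("need more pairs than adjustment covariates + 2")
    counts = m.reuse_counts
    if len(counts) < len(cols) + 5:
        # outcome model on a handful of distinct controls extrapolates
        # wildly at the treated covariates; report the raw effects instead
        warnings.warn("too few distinct matched controls for a stable "
                      "bias adjustment; returning raw pair effects")
        return float(np.mean(m.tt)), m.tt.copy()
    Xc = sample.loc[counts.index, cols].to_numpy(dtype=float)
    yc = sample.loc[counts.index, "y_loss"].to_numpy(dtype=float)
    w = counts.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(Xc)), Xc])
    sw = np.sqrt(w)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("collinear bias-adjustment design; using minimum-norm "
                      "least squares (redundant columns dropped)")
    beta, *_ = np.linalg.lstsq(design * sw[:, None], yc * sw, rcond=None)

    def mu(df_ids):
        X = sample.loc[df_ids, cols].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(X)), X]) @ beta

    gap = mu(m.treated_ids) - mu(m.control_ids)
    tt_adj = m.tt - gap
    return float(np.mean(tt_adj)), tt_adj


def att_variance(m: MatchedSample, mode: str = "plain",
                 sample: Optional[pd.DataFrame] = None,
                 covariates: Sequence[str] = COVARIATES,
                 tt: Optional[np.ndarray] = None,
                 ) -> Tuple[float, Dict[int, Tuple[float, float]]]:
    """Standard error and 90/95/99% normal CIs for the matched ATT.

    ``plain``: matched-pair variance ``sd(tt)/sqrt(n)`` inflated by the
    control-reuse factor ``sqrt(sum K_j^2 / sum K_j)`` (1 when no control
    is reused). ``heteroscedastic``: unit-level conditional variances
    estimated from each unit's nearest same-group neighbor in the
    (whitened) covariate space, combined with reuse weights in the
    matched-sample variance formula.

    ``tt`` defaults to the raw pair effects; pass the bias-adjusted vector
    to center the intervals on the adjusted ATT.
    """
    if len(m) < 2:
        raise ValueError("standard error undefined for fewer than 2 pairs")
    tt = m.tt if tt is None else np.asarray(tt, dtype=float)
    att = float(np.mean(tt))
    n = len(tt)
    K = m.reuse_counts.to_numpy(dtype=float)

    if mode == "plain":
        inflation = float((K ** 2).sum() / K.sum())
        se = float(np.std(tt, ddof=1) / np.sqrt(n) * np.sqrt(inflation))
    elif mode == "heteroscedastic":
        if sample is None:
            raise ValueError("heteroscedastic mode needs the pixel table")
        se = _heteroscedastic_se(m, sample, covariates)
    else:
        raise ValueError(f"unknown variance mode: {mode}")

    cis = {}
    for level in CI_LEVELS:
        z = stats.norm.ppf(0.5 + level / 200.0)
        cis[level] = (att - z * se, att + z * se)
    return se, cis


def _heteroscedastic_se(m: MatchedSample, sample: pd.DataFrame,
                        covariates: Sequence[str]) -> float:
    """Matched-sample SE with nearest-neighbor conditional variances.

    ``sigma^2_i = (Y_i - Y_nn(i))^2 / 2`` with the neighbor drawn from the
    unit's own group (treated or matched control); the ATT variance is
    ``n^-2 [ sum_treated sigma^2_i + sum_controls K_j^2 sigma^2_j ]``.
    """
    t_ids = np.unique(m.treated_ids)
    counts = m.reuse_counts
    c_ids = counts.index.to_numpy()
    both = np.concatenate([t_ids, c_ids])
    X = sample.loc[both, list(covariates)].to_numpy(dtype=float)
    VI = pooled_inverse_covariance(X)
    W = _whiten(X, VI)
    y = sample.loc[both, "y_loss"].to_numpy(dtype=float)

    def group_sigma2(sl: slice) -> np.ndarray:
        Wg, yg = W[sl], y[sl]
        if len(Wg) < 2:
            return np.zeros(len(Wg))
        D = cdist(Wg, Wg)
        np.fill_diagonal(D, np.inf)
        nn = np.argmin(D, axis=1)
        return (yg - yg[nn]) ** 2 / 2.0

    s2_t = group_sigma2(slice(0, len(t_ids)))
    s2_c = group_sigma2(slice(len(t_ids), len(both)))
    n = len(m)
    K = counts.to_numpy(dtype=float)
    var = (s2_t.sum() + (K ** 2 * s2_c).sum()) / n ** 2
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Estimator selection and comparison orchestration
# ---------------------------------------------------------------------------

def select_estimator(sample: pd.DataFrame, treated_mask: np.ndarray,
                     covariates: Sequence[str] = COVARIATES,
                     lps: Optional[pd.Series] = None,
                     candidates: Sequence[str] = METRICS,
                     different_property: bool = True,
                     k: int = 1,
                     balance_covariates: Optional[Sequence[str]] = None):
    """Run matching under each candidate metric; keep the best-balanced one.

    Balance is summarized by the maximum absolute post-match normalized
    difference (ties broken by the mean absolute value, then by candidate
    declaration order), assessed over ``balance_covariates`` (defaults to
    the matching covariates). Returns ``(metric, MatchedSample, balance
    rows)``. Raises :class:`MatchingInfeasibleError` if no candidate
    yields pairs.
    """
    if balance_covariates is None:
        balance_covariates = covariates
    if len(candidates) < 1:
        raise ValueError("need at least one candidate metric")
    results = []
    for metric in candidates:
        try:
            m = match_nearest_neighbor(
                sample, treated_mask, covariates, metric=metric, lps=lps,
                different_property=different_property, k=k)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if len(m) == 0:
            continue
        rows = balance_mod.balance_table(sample, treated_mask,
                                         balance_covariates, matched=m)
        results.append((balance_mod.max_abs_nd(rows),
                        balance_mod.mean_abs_nd(rows), metric, m, rows))
    if not results:
        raise MatchingInfeasibleError(
            "NA: very unbalanced covariate distributions")
    results.sort(key=lambda r: (r[0], r[1]))
    _, _, metric, m, rows = results[0]
    return metric, m, rows


@dataclass
class ComparisonSpec:
    """Treated/control definition for one matched comparison.

    question: ``A`` protected vs fully-unprotected across all tenures;
    ``B`` protected vs fully-unprotected within one tenure; ``C`` one
    tenure vs another within a protection stratum; ``spillover``
    unprotected parts of protected properties vs fully-unprotected
    properties within one tenure.
    """

    question: str
    biome: str
    tenure: Optional[str] = None              # B / spillover
    treated_tenure: Optional[str] = None      # C
    control_tenure: Optional[str] = None      # C
    protection_stratum: Optional[str] = None  # C: protected | unprotected

    @property
    def label(self) -> str:
        parts = [self.question, self.biome]
        for x in (self.tenure, self.treated_tenure, self.control_tenure,
                  self.protection_stratum):
            if x:
                parts.append(x)
        return "_".join(parts)


@dataclass
class ATTEstimate:
    """Raw and bias-adjusted ATT with matched-sample bookkeeping."""

    label: str
    biome: str
    mean_treated: float = np.nan
    mean_control: float = np.nan
    raw_att: float = np.nan
    bias_adjusted_att: float = np.nan
    se: float = np.nan
    cis: Dict[int, Tuple[float, float]] = field(default_factory=dict)
    variance_mode: str = "plain"
    metric: Optional[str] = None
    n_t: int = 0
    n_mc: int = 0
    n_cp: int = 0
    na_reason: Optional[str] = None
    matched: Optional[MatchedSample] = None
    balance_pre: Optional[list] = None
    balance_post: Optional[list] = None

    @property
    def is_na(self) -> bool:
        return self.na_reason is not None

    def significant(self, level: int = 90) -> bool:
        if self.is_na:
            return False
        lo, hi = self.cis[level]
        return lo > 0 or hi < 0

    def to_row(self) -> dict:
        row = {
            "comparison": self.label,
            "biome": self.biome,
            "mean_treated": self.mean_treated,
            "mean_control": self.mean_control,
            "raw_att": self.raw_att,
            "bias_adjusted_att": self.bias_adjusted_att,
            "se": self.se,
            "variance_mode": self.variance_mode,
            "metric": self.metric,
            "n_t": self.n_t,
            "n_mc": self.n_mc,
            "n_cp": self.n_cp,
            "na_reason": self.na_reason,
        }
        for level, (lo, hi) in self.cis.items():
            row[f"ci{level}_lo"], row[f"ci{level}_hi"] = lo, hi
        return row


def _arm_masks(sample: pd.DataFrame, spec: ComparisonSpec):
    pc = sample["protection_class"]
    q = spec.question
    if q == "A":
        t = pc == "protected"
        c = pc == "fully_unprotected"
    elif q == "B":
        t = (pc == "protected") & (sample["tenure"] == spec.tenure)
        c = (pc == "fully_unprotected") & (sample["tenure"] == spec.tenure)
    elif q == "spillover":
        t = pc == "unprotected_part_of_protected_property"
        c = pc == "fully_unprotected"
        if spec.tenure is not None:  # tenure=None pools the regimes
            t &= sample["tenure"] == spec.tenure
            c &= sample["tenure"] == spec.tenure
    elif q == "C":
        stratum_class = ("protected" if spec.protection_stratum == "protected"
                         else "fully_unprotected")
        t = (pc == stratum_class) & (sample["tenure"] == spec.treated_tenure)
        c = (pc == stratum_class) & (sample["tenure"] == spec.control_tenure)
    else:
        raise ValueError(f"unknown question: {q}")
    return t.to_numpy(), c.to_numpy()


def run_comparison(sample: pd.DataFrame, spec: ComparisonSpec,
                   covariates: Sequence[str] = COVARIATES,
                   caliper_sd: float = 0.25,
                   variance_mode: str = "plain",
                   candidates: Sequence[str] = METRICS,
                   min_treated: int = MIN_TREATED,
                   k: int = 1,
                   spillover_pool: Optional[pd.DataFrame] = None,
                   ) -> ATTEstimate:
    """Full matched comparison: propensity -> trim -> match -> ATT.

    ``spillover_pool`` supplies the pixels from unprotected parts of
    protected properties (kept out of the main sample by the study-frame
    exclusions) when ``spec.question == "spillover"``.
    """
    frame = sample
    if spec.question == "spillover" and spillover_pool is not None:
        frame = pd.concat([sample, spillover_pool])
    frame = frame[frame["biome"] == spec.biome]
    est = ATTEstimate(label=spec.label, biome=spec.biome,
                      variance_mode=variance_mode)

    t_mask, c_mask = _arm_masks(frame, spec)
    est.n_cp = int(c_mask.sum())
    if t_mask.sum() == 0 or c_mask.sum() == 0:
        est.na_reason = "NA: empty treatment or control arm"
        return est
    if t_mask.sum() < min_treated:
        est.na_reason = "NA: very small treated pool"
        return est
    if c_mask.sum() < 2:
        est.na_reason = "NA: very small control pool"
        return est

    arm = frame[t_mask | c_mask].copy()
    treated = t_mask[t_mask | c_mask]
    est.mean_treated = float(arm.loc[treated, "y_loss"].mean())
    est.mean_control = float(arm.loc[~treated, "y_loss"].mean())

    try:
        fit = propensity_mod.fit_propensity(arm, treated, covariates,
                                            label=spec.label)
        support, _ = propensity_mod.trim_common_support(
            arm, treated, fit, caliper_sd=caliper_sd)
    except (propensity_mod.SeparationError,
            propensity_mod.TrimmingError) as exc:
        est.na_reason = f"NA: {exc}"
        return est
    arm_s = arm[support]
    treated_s = treated[support]
    lps = fit.lps

    est.balance_pre = balance_mod.balance_table(arm_s, treated_s, covariates)
    try:
        metric, m, post_rows = select_estimator(
            arm_s, treated_s, covariates, lps=lps, candidates=candidates,
            different_property=True, k=k)
    except MatchingInfeasibleError as exc:
        est.na_reason = str(exc)
        return est
    if all(r.flag == "imbalanced" for r in post_rows):
        est.na_reason = "NA: very unbalanced covariate distributions"
        est.balance_post = post_rows
        return est

    est.metric = metric
    est.matched = m
    est.balance_post = post_rows
    est.n_t = len(np.unique(m.treated_ids))
    est.n_mc = m.n_matched_controls
    est.raw_att = raw_att(m)
    try:
        est.bias_adjusted_att, tt_adj = bias_adjust(m, arm_s, covariates)
    except ValueError:
        est.bias_adjusted_att, tt_adj = est.raw_att, m.tt
    est.se, est.cis = att_variance(m, mode=variance_mode, sample=arm_s,
                                   covariates=covariates, tt=tt_adj)
    return est
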