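"""Per-study odds ratios and fixed/random-effects pooling on the log-OR scale.

The pooling machinery is the classic inverse-variance toolkit:

* per-study log odds ratio with Woolf variance ``1/a + 1/b + 1/c + 1/d``,
  Haldane-Anscombe 0.5 correction applied to all four cells only when a
  zero cell occurs;
* fixed-effects pooling with weights ``w_i = 1/se_i^2``;
* Cochran's Q with its chi-square p-value (P_h) on k - 1 df, I^2 and the
  DerSimonian-Laird moment estimator of the between-study variance tau^2;
* random-effects pooling with weights ``1/(se_i^2 + tau^2)``;
* the heterogeneity-driven rule: random effects when P_h < 0.05, fixed
  otherwise (threshold configurable);
* a Mantel-Haenszel fixed-effects pooled OR as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (EstimationError, HeterogeneityUndefinedError,
                     InsufficientStudiesError)
from .genetic_models import ContrastTable

#: Two-sided 95% standard-normal quantile used for every confidence interval.
Z_95 = 1.959964


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio with its Woolf standard error."""

    study_id: str
    log_or: float
    se: float
    corrected: bool = False

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z_95 * self.se)

    @property
    def variance(self) -> float:
        return self.se ** 2


@dataclass(frozen=True)
class PooledResult:
    """Pooled odds ratio with heterogeneity statistics.

    ``q``, ``p_h``, ``i2`` and ``tau2`` are NaN when k < 2 (heterogeneity
    undefined); ``model_used`` is then "fixed".
    """

    k: int
    model_used: str          # "fixed" | "random"
    log_or: float
    se: float
    z: float
    p: float
    q: float
    p_h: float
    i2: float
    tau2: float
    n_case: int = 0
    n_control: int = 0

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z_95 * self.se)


def study_log_or(t: ContrastTable, correction: float = 0.5,
                 study_id: str = "") -> EffectEstimate:
    """Log odds ratio ``ln(ad/bc)`` of one 2x2 table with Woolf variance.

    If any cell is zero, ``correction`` (Haldane-Anscombe, default 0.5) is
    added to all four cells and the estimate flagged as corrected.  A table
    with an empty arm (a = b = 0 or c = d = 0) is not estimable.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if a + b == 0 or c + d == 0:
        raise EstimationError(
            f"study {study_id!r}: empty arm in 2x2 table "
            f"({t.a}, {t.b}, {t.c}, {t.d})")
    corrected = False
    if min(a, b, c, d) == 0:
        if correction <= 0:
            raise EstimationError(
                f"study {study_id!r}: zero cell and no continuity correction")
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
        corrected = True
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(study_id=study_id, log_or=log_or, se=se,
                          corrected=corrected)


def _weighted_pool(thetas: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    pooled = float(np.sum(weights * thetas) / np.sum(weights))
    se = float(1.0 / math.sqrt(np.sum(weights)))
    return pooled, se


def _as_arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) == 0:
        raise InsufficientStudiesError("no studies to pool")
    thetas = np.array([e.log_or for e in effects], dtype=float)
    variances = np.array([e.variance for e in effects], dtype=float)
    return thetas, variances


def pool_fixed(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Inverse-variance fixed-effects pooled (log-OR, se)."""
    thetas, variances = _as_arrays(effects)
    return _weighted_pool(thetas, 1.0 / variances)


def pool_random(effects: Sequence[EffectEstimate],
                tau2: float) -> tuple[float, float]:
    """Random-effects pooled (log-OR, se) with weights ``1/(v_i + tau2)``."""
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    thetas, variances = _as_arrays(effects)
    return _weighted_pool(thetas, 1.0 / (variances + tau2))


def cochran_q(effects: Sequence[EffectEstimate],
              fixed_pooled_log_or: float | None = None) -> tuple[float, float]:
    """Cochran's heterogeneity statistic Q and its p-value P_h (k - 1 df)."""
    if len(effects) < 2:
        raise HeterogeneityUndefinedError(
            f"Q requires at least 2 studies, got {len(effects)}")
    thetas, variances = _as_arrays(effects)
    if fixed_pooled_log_or is None:
        fixed_pooled_log_or, _ = pool_fixed(effects)
    w = 1.0 / variances
    q = float(np.sum(w * (thetas - fixed_pooled_log_or) ** 2))
    p_h = float(stats.chi2.sf(q, df=len(effects) - 1))
    return q, p_h


def i_squared(q: float, k: int) -> float:
    """Higgins I^2 = max(0, (Q - (k-1)) / Q); the 0/0 case is defined as 0."""
    if k < 2:
        raise HeterogeneityUndefinedError("I^2 requires k >= 2")
    if q <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q)


def dl_tau2(effects: Sequence[EffectEstimate], q: float | None = None) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance.

    ``tau2 = max(0, (Q - (k-1)) / c)`` with ``c = sum(w) - sum(w^2)/sum(w)``.
    """
    if len(effects) < 2:
        raise HeterogeneityUndefinedError("tau^2 requires k >= 2")
    thetas, variances = _as_arrays(effects)
    if q is None:
        q, _ = cochran_q(effects)
    w = 1.0 / variances
    c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - (len(effects) - 1)) / c)


def z_test(pooled_log_or: float, pooled_se: float) -> tuple[float, float]:
    """Wald Z statistic and its two-sided normal p-value."""
    if pooled_se <= 0:
        raise ValueError("pooled se must be positive")
    z = pooled_log_or / pooled_se
    return z, float(2.0 * stats.norm.sf(abs(z)))


def select_model(p_h: float | None, k: int, threshold: float = 0.05) -> str:
    """Heterogeneity-driven model choice: random when P_h < threshold.

    With a single study (heterogeneity undefined) the fixed model is used.
    """
    if k < 2 or p_h is None or math.isnan(p_h):
        return "fixed"
    return "random" if p_h < threshold else "fixed"


def meta_analyse(effects: Sequence[EffectEstimate],
                 het_threshold: float = 0.05,
                 n_case: int = 0, n_control: int = 0) -> PooledResult:
    """Full pooling pipeline for one collection of study effects.

    Computes Q/P_h/I^2/tau^2, chooses fixed vs random effects by the
    heterogeneity rule, and returns the pooled OR with its Z-test.
    """
    k = len(effects)
    if k == 0:
        raise InsufficientStudiesError("no studies to pool")
    if k == 1:
        q = p_h = i2 = tau2 = float("nan")
        model = "fixed"
        log_or, se = pool_fixed(effects)
    else:
        log_or_f, se_f = pool_fixed(effects)
        q, p_h = cochran_q(effects, log_or_f)
        i2 = i_squared(q, k)
        tau2 = dl_tau2(effects, q)
        model = select_model(p_h, k, het_threshold)
        if model == "random":
            log_or, se = pool_random(effects, tau2)
        else:
            log_or, se = log_or_f, se_f
    z, p = z_test(log_or, se)
    return PooledResult(k=k, model_used=model, log_or=log_or, se=se, z=z, p=p,
                        q=q, p_h=p_h, i2=i2, tau2=tau2,
                        n_case=n_case, n_control=n_control)


def pool_fixed_mh(tables: Sequence[ContrastTable]) -> tuple[float, float, float]:
    """Mantel-Haenszel pooled OR with 95% CI (independent cross-check).

    Delegates to statsmodels' stratified-table machinery (MH pooled OR and
    the variance of its log by the Robins-Breslow-Greenland formula).
    Returns (OR, ci_low, ci_high).
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    if len(tables) == 0:
        raise InsufficientStudiesError("no tables to pool")
    strata = np.array([[[t.a, t.b], [t.c, t.d]] for t in tables],
                      dtype=float).T  # shape (2, 2, k)
    st = StratifiedTable(strata)
    or_mh = float(st.oddsratio_pooled)
    if not math.isfinite(or_mh) or or_mh <= 0:
        raise EstimationError("Mantel-Haenszel pooled OR is degenerate")
    lcb, ucb = st.oddsratio_pooled_confint(alpha=0.05)
    return or_mh, float(lcb), float(ucb)
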