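"""Publication-bias diagnostics: Begg's rank correlation and Egger's regression.

Begg's adjusted rank-correlation test computes, for each study, the deviate
of its effect from the fixed-effects pooled value standardized by the
variance of that deviation, then tests for Kendall correlation between the
deviates and the study variances.  Egger's test regresses the standardized
effect ``theta_i / se_i`` on precision ``1 / se_i`` (unweighted, classic
form) and tests the intercept against zero with a t distribution on k - 2
degrees of freedom.  Both look for small-study effects: an association
between effect size and precision that a symmetric funnel would not show.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientStudiesError
from .meta_core import EffectEstimate, pool_fixed

#: Floor for the variance radicand in Begg deviates; a study whose variance
#: is numerically at or below the pooled variance would otherwise yield an
#: imaginary deviate.
_VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class BiasTestResult:
    method: str              # "begg" | "egger"
    statistic: float         # Kendall tau (begg) or intercept (egger)
    z_or_t: float
    p: float
    k: int
    standard_error: float = float("nan")   # egger only
    variance_floored: bool = False         # begg only


def begg_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Begg's adjusted rank-correlation test for funnel asymmetry."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Begg's test requires k >= 3, got {k}")
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    pooled, pooled_se = pool_fixed(effects)
    v_pooled = pooled_se ** 2
    radicand = v - v_pooled
    floored = bool(np.any(radicand <= _VARIANCE_FLOOR))
    radicand = np.maximum(radicand, _VARIANCE_FLOOR)
    deviates = (theta - pooled) / np.sqrt(radicand)
    tau = float(stats.kendalltau(deviates, v).statistic)  # tau-b handles ties
    z = tau / math.sqrt(2.0 * (2 * k + 5) / (9.0 * k * (k - 1)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BiasTestResult(method="begg", statistic=tau, z_or_t=z, p=p, k=k,
                          variance_floored=floored)


def egger_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's linear-regression test for funnel asymmetry."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test requires k >= 3, got {k}")
    se = np.array([e.se for e in effects])
    if np.ptp(se) == 0:
        raise InsufficientStudiesError(
            "Egger's test is degenerate when all standard errors are equal")
    theta = np.array([e.log_or for e in effects])
    y = theta / se                      # standardized effect
    x = 1.0 / se                        # precision
    design = np.column_stack([np.ones(k), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    intercept = float(coef[0])
    fitted = design @ coef
    rss = float(np.sum((y - fitted) ** 2))
    scale = max(float(np.sum(y ** 2)), 1.0)
    if rss <= 1e-12 * scale:
        # numerically exact linear fit: the intercept is known without
        # error, so the test degenerates
        exact_zero = abs(intercept) <= 1e-8 * math.sqrt(scale)
        return BiasTestResult(
            method="egger",
            statistic=0.0 if exact_zero else intercept,
            z_or_t=0.0 if exact_zero else math.copysign(math.inf, intercept),
            p=1.0 if exact_zero else 0.0, k=k, standard_error=0.0)
    sigma2 = rss / (k - 2)
    xtx_inv = np.linalg.inv(design.T @ design)
    se_intercept = math.sqrt(sigma2 * xtx_inv[0, 0])
    t = intercept / se_intercept
    p = float(2.0 * stats.t.sf(abs(t), df=k - 2))
    return BiasTestResult(method="egger", statistic=intercept, z_or_t=t, p=p,
                          k=k, standard_error=se_intercept)
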