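"""Monte-Carlo calibration experiments for the pooling and bias machinery.

These experiments check that the toolkit behaves as advertised under its
own generative model: the HWE test rejects at its nominal rate on true-HWE
controls, the publication-bias tests hold their size on symmetric funnels
and gain power under suppression, and the inverse-variance fixed-effects
pooled OR agrees with the Mantel-Haenszel estimate on large balanced
collections.  Every experiment takes a seed and is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bias_diagnostics import begg_test, egger_test
from .errors import InsufficientStudiesError
from .genetic_models import contrast_table, hwe_chi_square
from .meta_core import pool_fixed, pool_fixed_mh, study_log_or
from .study_io import GenotypeCounts
from .synthetic_data import SimulationConfig, _derive_seed, simulate_studies


@dataclass(frozen=True)
class RejectionRate:
    rate: float
    replicates: int

    def binomial_band(self, p0: float = 0.05) -> tuple[float, float]:
        """95% acceptance band for an observed proportion when the true
        rejection probability is ``p0``."""
        half = 1.959964 * math.sqrt(p0 * (1 - p0) / self.replicates)
        return (p0 - half, p0 + half)


def hwe_rejection_rate(replicates: int = 1000, n_controls: int = 2000,
                       allele_freq_range: tuple[float, float] = (0.20, 0.45),
                       alpha: float = 0.05, seed: int = 0) -> RejectionRate:
    """Type-I error of the HWE chi-square on controls sampled under HWE."""
    rng = np.random.default_rng([seed, 0x48574531])
    rejections = 0
    for _ in range(replicates):
        q = rng.uniform(*allele_freq_range)
        counts = rng.multinomial(
            n_controls, [q * q, 2 * q * (1 - q), (1 - q) ** 2])
        if hwe_chi_square(GenotypeCounts(*map(int, counts))).p < alpha:
            rejections += 1
    return RejectionRate(rejections / replicates, replicates)


def _dominant_effects(records):
    effects = []
    for r in records:
        t = contrast_table(r.cases, r.controls, "dominant")
        effects.append(study_log_or(t, study_id=r.study_id))
    return effects


def bias_test_rejection_rates(replicates: int = 1000, k: int = 20,
                              or_common: float = 1.0, tau: float = 0.0,
                              suppression: tuple[float, float] | None = None,
                              alpha: float = 0.05,
                              seed: int = 0) -> dict[str, RejectionRate]:
    """Begg/Egger rejection rates on simulated funnels.

    With ``or_common = 1`` and no suppression the funnels are symmetric and
    the rates estimate the tests' size; with suppression of non-significant
    studies they estimate power against small-study bias.  Replicates whose
    surviving collection is too small (or degenerate) for a test do not
    count toward that test's denominator.
    """
    counts = {"begg": 0, "egger": 0}
    used = {"begg": 0, "egger": 0}
    for rep in range(replicates):
        config = SimulationConfig(
            k=k, or_het=or_common, or_hom=or_common, tau=tau,
            suppression=suppression, seed=_derive_seed(seed, rep))
        effects = _dominant_effects(simulate_studies(config))
        for name, test in (("begg", begg_test), ("egger", egger_test)):
            try:
                result = test(effects)
            except InsufficientStudiesError:
                continue
            used[name] += 1
            if result.p < alpha:
                counts[name] += 1
    return {name: RejectionRate(counts[name] / used[name], used[name])
            for name in counts}


def mh_iv_agreement(collections: int = 20, k: int = 20,
                    n_range: tuple[int, int] = (200, 800),
                    or_common: float = 1.2,
                    seed: int = 0) -> float:
    """Worst relative difference between the inverse-variance and
    Mantel-Haenszel fixed-effects pooled ORs across simulated balanced
    study collections."""
    worst = 0.0
    for rep in range(collections):
        config = SimulationConfig(
            k=k, or_het=or_common, or_hom=or_common, tau=0.0,
            n_case_range=n_range, n_control_range=n_range,
            seed=_derive_seed(seed, rep))
        records = simulate_studies(config)
        tables = [contrast_table(r.cases, r.controls, "dominant")
                  for r in records]
        log_or_iv, _ = pool_fixed([study_log_or(t) for t in tables])
        or_mh, _, _ = pool_fixed_mh(tables)
        worst = max(worst, abs(math.exp(log_or_iv) - or_mh) / or_mh)
    return worst
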