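"""Closed-form rejection rates via the noncentral t distribution.

Under the generative model the proxy group-mean difference is
``x1*Delta + x2*delta`` with common within-group SD ``sigma_P``, so the
two-sample t statistic is approximately noncentral t with

    d      = (x1*Delta + x2*delta) / sigma_P
    lambda = d * sqrt(n_a * n_b / (n_a + n_b))
    df     = n_a + n_b - 2

(group variances are equal by construction, so the pooled df is used; the
Monte Carlo engine remains the ground truth where the Welch df differs at
small unequal n).  This module is the independent cross-check for the
Monte Carlo engine, and a fast analytic companion on sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .model_core import ReducedParams

__all__ = ["EffectSummary", "effect_summary", "analytic_rate"]


@dataclass(frozen=True)
class EffectSummary:
    """Standardized effect and noncentrality implied by a parameter set."""

    d: float        # proxy-scale standardized mean shift
    lam: float      # noncentrality parameter
    df: float       # pooled degrees of freedom
    t_crit: float   # two-sided critical value at alpha


def effect_summary(params: ReducedParams) -> EffectSummary:
    coeffs = params.coefficients()
    shift = coeffs.x1 * params.Delta + coeffs.x2 * params.delta
    d = shift / params.sigma_P
    n_a, n_b = params.n_a, params.n_b
    lam = d * math.sqrt(n_a * n_b / (n_a + n_b))
    df = n_a + n_b - 2
    t_crit = stats.t.ppf(1.0 - params.alpha / 2.0, df)
    return EffectSummary(d=d, lam=lam, df=df, t_crit=t_crit)


def rejection_probability(params: ReducedParams) -> float:
    """P(|T'| > t_crit) for noncentral t with the implied df and lambda."""
    es = effect_summary(params)
    if es.lam == 0.0:
        return float(params.alpha)
    upper = stats.nct.sf(es.t_crit, es.df, es.lam)
    lower = stats.nct.cdf(-es.t_crit, es.df, es.lam)
    return float(upper + lower)


def analytic_rate(params: ReducedParams) -> float:
    """Closed-form FPR (Delta = 0) or FNR (Delta != 0).

    Mirrors the regime convention of the Monte Carlo engine: the FPR is
    the rejection probability under Delta = 0 (exactly alpha when delta is
    also 0), and the FNR is one minus the rejection probability when a
    true effect is present.
    """
    p_reject = rejection_probability(params)
    if params.Delta != 0.0:
        return 1.0 - p_reject
    return p_reject
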