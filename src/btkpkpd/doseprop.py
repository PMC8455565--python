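"""Dose-proportionality statistics and PD-efficacy correlation.

The power model regresses ln(exposure) on ln(dose),

    ln(AUC or Cmax) = beta0 + beta1 * ln(dose),

and declares proportionality when the 90% confidence interval for beta1
lies entirely inside an acceptance interval derived from bioequivalence
limits (theta_L, theta_U) and the study's dose ratio r:

    (1 + ln(theta_L)/ln(r),  1 + ln(theta_U)/ln(r)).

With the conventional limits (0.80, 1.25) and a 10-fold dose range this
gives the familiar 0.90-1.10 band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import ValidationError

__all__ = [
    "PowerModelFit",
    "CorrelationResult",
    "fit_power_model",
    "acceptance_range",
    "pd_efficacy_correlation",
]

DEFAULT_BE_LIMITS = (0.80, 1.25)


@dataclass(frozen=True)
class PowerModelFit:
    beta0: float
    beta1: float
    ci90: tuple[float, float]
    acceptance_range: tuple[float, float]
    verdict: str  # proportional | nonproportional | inconclusive
    n: int
    se_beta1: float

    def __str__(self) -> str:
        lo, hi = self.ci90
        alo, ahi = self.acceptance_range
        return (
            f"beta1 = {self.beta1:.3f} (90% CI {lo:.3f}-{hi:.3f}); "
            f"acceptance {alo:.2f}-{ahi:.2f}; {self.verdict} (n={self.n})"
        )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    n: int
    p_value: float


def acceptance_range(
    dose_ratio: float,
    be_limits: tuple[float, float] = DEFAULT_BE_LIMITS,
) -> tuple[float, float]:
    """Acceptance interval for the power-model slope beta1."""
    low, high = be_limits
    if dose_ratio <= 1:
        raise ValidationError(f"dose_ratio must be > 1, got {dose_ratio}")
    if not (0 < low < 1 < high):
        raise ValidationError(f"bioequivalence limits must straddle 1, got {be_limits}")
    ln_r = math.log(dose_ratio)
    return (1 + math.log(low) / ln_r, 1 + math.log(high) / ln_r)


def fit_power_model(
    doses: Sequence[float],
    values: Sequence[float],
    ci_level: float = 0.90,
    be_limits: tuple[float, float] = DEFAULT_BE_LIMITS,
) -> PowerModelFit:
    """OLS fit of the power model with a CI-inclusion proportionality verdict.

    ``values`` are per-observation exposures (AUC or Cmax, > 0) at the
    paired ``doses``.  The verdict is "proportional" when the CI is inside
    the acceptance range, "nonproportional" when the two are disjoint, and
    "inconclusive" otherwise.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.shape != v.shape or d.ndim != 1:
        raise ValidationError("doses and values must be 1-D and equally long")
    if d.size < 3:
        raise ValidationError("need >= 3 observations")
    if np.unique(d).size < 2:
        raise ValidationError("need >= 2 distinct dose levels")
    if np.any(d <= 0) or np.any(v <= 0):
        raise ValidationError("doses and values must be > 0 (log scale)")

    x = np.log(d)
    y = np.log(v)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    beta0, beta1 = fit.params
    se_beta1 = float(fit.bse[1])
    dfree = d.size - 2
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, dfree)
    ci = (float(beta1 - tcrit * se_beta1), float(beta1 + tcrit * se_beta1))

    accept = acceptance_range(float(d.max() / d.min()), be_limits)
    if accept[0] <= ci[0] and ci[1] <= accept[1]:
        verdict = "proportional"
    elif ci[1] < accept[0] or ci[0] > accept[1]:
        verdict = "nonproportional"
    else:
        verdict = "inconclusive"

    return PowerModelFit(
        beta0=float(beta0),
        beta1=float(beta1),
        ci90=ci,
        acceptance_range=accept,
        verdict=verdict,
        n=int(d.size),
        se_beta1=se_beta1,
    )


def pd_efficacy_correlation(
    scores: Sequence[float],
    markers: Sequence[float],
) -> CorrelationResult:
    """Pearson correlation and OLS line between efficacy scores and a PD
    marker (occupancy% expected negative, phospho-target% positive).

    The sign is reported as-is; the regression is marker on score.
    """
    s = np.asarray(scores, dtype=float)
    m = np.asarray(markers, dtype=float)
    if s.shape != m.shape or s.ndim != 1:
        raise ValidationError("scores and markers must be 1-D and equally long")
    if s.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.std(s) == 0 or np.std(m) == 0:
        raise ValidationError("zero variance in scores or markers")
    lr = stats.linregress(s, m)
    return CorrelationResult(
        r=float(lr.rvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=int(s.size),
        p_value=float(lr.pvalue),
    )
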