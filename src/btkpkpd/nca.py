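"""Noncompartmental analysis and dose-normalised exposure ratios.

Conventions follow standard NCA practice for sparse small-animal and
phase I data:

* AUClast by the linear trapezoid up to the last quantifiable observation
  (a lin-up/log-down option is available for steeply declining profiles);
* BLQ handling: below-quantification samples before Tmax are set to zero,
  BLQ samples after Tmax are excluded;
* the terminal slope lambda_z from a log-linear regression on the last
  quantifiable points (3 by default, never including Tmax), with the
  adjusted R^2 reported;
* AUCinf = AUClast + Clast/lambda_z.

Dose-group exposure ratios are normalised to the lowest dose group and
rounded half-up to one decimal, which is the arithmetic that turns group
mean AUCs of 2.0/10.0/49.9 into the ratio 1.0 : 5.0 : 25.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .core import ValidationError

__all__ = ["NCAResult", "compute_nca", "dose_normalized_ratios"]


@dataclass(frozen=True)
class NCAResult:
    Cmax: float
    Tmax: float
    AUClast: float
    lambda_z: float | None        # 1/h; None when not estimable
    AUCinf: float | None          # ng.h/mL; None when lambda_z is not estimable
    n_points_lambda_z: int
    r2_adj: float | None = None

    @property
    def half_life(self) -> float | None:
        if self.lambda_z is None or self.lambda_z <= 0:
            return None
        return math.log(2.0) / self.lambda_z


def _auc_segment(t0: float, t1: float, c0: float, c1: float, method: str) -> float:
    dt = t1 - t0
    if method == "linear" or c1 >= c0 or c0 <= 0 or c1 <= 0:
        return dt * (c0 + c1) / 2.0
    # log-down trapezoid for declining positive segments
    return dt * (c0 - c1) / math.log(c0 / c1)


def compute_nca(
    times: Sequence[float],
    concs: Sequence[float],
    blq_flags: Sequence[bool] | None = None,
    auc_method: str = "linear",
    n_lambda_z: int = 3,
) -> NCAResult:
    """Noncompartmental summary of a single concentration-time profile.

    Parameters
    ----------
    times, concs
        Observation times (h, strictly increasing) and concentrations
        (ng/mL).
    blq_flags
        Per-observation below-LLOQ flags; omitted means all quantifiable.
    auc_method
        ``"linear"`` (default) or ``"lin-up-log-down"``.
    n_lambda_z
        Number of terminal quantifiable points for the lambda_z
        regression (Tmax excluded).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValidationError("times and concs must be 1-D and equally long")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if auc_method not in ("linear", "lin-up-log-down"):
        raise ValidationError(f"unknown AUC method {auc_method!r}")
    blq = (
        np.zeros(t.size, dtype=bool)
        if blq_flags is None
        else np.asarray(blq_flags, dtype=bool)
    )
    if blq.shape != t.shape:
        raise ValidationError("blq_flags length mismatch")

    quant = ~blq
    if quant.sum() < 3:
        raise ValidationError(
            f"need >= 3 quantifiable observations, got {int(quant.sum())}"
        )

    i_tmax = int(np.argmax(np.where(quant, c, -np.inf)))
    cmax, tmax = float(c[i_tmax]), float(t[i_tmax])

    # BLQ policy: zero before Tmax, excluded after
    use = quant | (t < tmax)
    t_use = t[use]
    c_use = np.where(blq[use], 0.0, c[use])

    # AUClast extends to the last quantifiable point
    last_q = np.max(np.nonzero(quant)[0])
    t_last = t[last_q]
    in_auc = t_use <= t_last
    t_auc, c_auc = t_use[in_auc], c_use[in_auc]
    method = "linear" if auc_method == "linear" else "log-down"
    auclast = sum(
        _auc_segment(t_auc[i], t_auc[i + 1], c_auc[i], c_auc[i + 1], method)
        for i in range(t_auc.size - 1)
    )

    # terminal slope on the last n quantifiable positive points after Tmax
    term_idx = [
        i for i in np.nonzero(quant)[0] if t[i] > tmax and c[i] > 0
    ][-n_lambda_z:]
    lambda_z = aucinf = r2_adj = None
    if len(term_idx) >= 2:
        tt = t[term_idx]
        ly = np.log(c[term_idx])
        slope, intercept = np.polyfit(tt, ly, 1)
        if slope < 0:
            lambda_z = float(-slope)
            pred = slope * tt + intercept
            ss_res = float(np.sum((ly - pred) ** 2))
            ss_tot = float(np.sum((ly - ly.mean()) ** 2))
            n = len(term_idx)
            if ss_tot > 0 and n > 2:
                r2 = 1 - ss_res / ss_tot
                r2_adj = float(1 - (1 - r2) * (n - 1) / (n - 2))
            clast = float(c[last_q])
            aucinf = float(auclast + clast / lambda_z)

    return NCAResult(
        Cmax=cmax,
        Tmax=tmax,
        AUClast=float(auclast),
        lambda_z=lambda_z,
        AUCinf=aucinf,
        n_points_lambda_z=len(term_idx) if lambda_z is not None else 0,
        r2_adj=r2_adj,
    )


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def dose_normalized_ratios(
    group_means: Mapping[float, Mapping[str, float]],
    decimals: int = 1,
) -> dict[str, dict[float, float]]:
    """Exposure ratios across dose groups, normalised to the lowest dose.

    ``group_means`` maps dose -> {metric -> group mean}; the result maps
    metric -> {dose -> ratio}.  Ratios are rounded half-up (49.9/2.0 =
    24.95 prints as 25.0).
    """
    if not group_means:
        raise ValidationError("group_means is empty")
    doses = sorted(group_means)
    ref = group_means[doses[0]]
    metrics = list(ref)
    out: dict[str, dict[float, float]] = {}
    for metric in metrics:
        ref_mean = ref[metric]
        if ref_mean is None or ref_mean <= 0:
            raise ValidationError(
                f"reference-group mean for {metric!r} must be > 0, got {ref_mean}"
            )
        out[metric] = {
            d: _round_half_up(group_means[d][metric] / ref_mean, decimals)
            for d in doses
        }
    return out
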