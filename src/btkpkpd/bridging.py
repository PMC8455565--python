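"""In vitro / in vivo bridging for dose selection.

Covalent-inhibitor potency in a fixed-time incubation assay follows

    kobs(C) = kinact * C / (KI + C),        occupancy = 1 - exp(-kobs * t),

so the apparent IC50 depends on the incubation time t: in the linear
(non-saturating) regime C << KI it satisfies C * t = ln2 * KI / kinact and
scales inversely with time.  This module provides that forward model, its
inversion (the in vitro concentration "equivalent" to an in vivo
steady-state occupancy), the time-rescaling of covalent IC50s, an
absolute-IC50 four-parameter-logistic fit against control-defined signal
windows, and sigmoid-Emax pathway-inhibition tables over a clinical dose
grid — the mechanistic front end of systems-pharmacology dose projection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, brentq, curve_fit

from .core import DosingRegimen, PKParameters, TurnoverParameters, ValidationError
from .occupancy import occupancy_summary, simulate_occupancy

__all__ = [
    "CovalentAssayModel",
    "EmaxModel",
    "FourPLFit",
    "invitro_occupancy",
    "covalent_ic50_time_scaling",
    "fit_4pl_absolute_ic50",
    "equivalent_invitro_concentration",
    "pathway_inhibition_table",
    "DEFAULT_DOSE_GRID",
]

DEFAULT_DOSE_GRID = (1.0, 3.0, 5.0, 10.0, 20.0, 30.0, 40.0)  # mg QD


@dataclass(frozen=True)
class CovalentAssayModel:
    """kinact/KI description of a fixed-incubation covalent occupancy assay."""

    kinact: float          # 1/h
    KI: float              # nM
    incubation_time: float  # h

    def __post_init__(self) -> None:
        for name in ("kinact", "KI", "incubation_time"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def ic50_linear(self) -> float:
        """Apparent IC50 (nM) in the non-saturating regime."""
        return math.log(2.0) * self.KI / (self.kinact * self.incubation_time)


@dataclass(frozen=True)
class EmaxModel:
    """Sigmoid maximal-inhibition model: emax * C^h / (ec50^h + C^h)."""

    emax: float
    ec50: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.emax <= 1:
            raise ValidationError(f"emax must lie in (0, 1], got {self.emax}")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValidationError("ec50 and hill must be > 0")

    def inhibition(self, conc: float | np.ndarray) -> float | np.ndarray:
        c = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ch = np.where(c > 0, c**self.hill, 0.0)
        val = self.emax * ch / (self.ec50**self.hill + ch)
        return float(val) if np.isscalar(conc) else val


@dataclass(frozen=True)
class FourPLFit:
    top: float
    bottom: float
    ic50_abs: float | None   # None when the curve never crosses mid-window
    hill: float
    ic50_rel: float          # inflection of the fitted logistic
    determinable: bool


def invitro_occupancy(C: float | np.ndarray, model: CovalentAssayModel) -> float | np.ndarray:
    """Fraction of target inactivated after the assay's incubation time."""
    c = np.asarray(C, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be >= 0")
    kobs = model.kinact * c / (model.KI + c)
    occ = 1.0 - np.exp(-kobs * model.incubation_time)
    return float(occ) if np.isscalar(C) else occ


def covalent_ic50_time_scaling(ic50_ref: float, t_ref: float, t_new: float) -> float:
    """Rescale a covalent IC50 between incubation times (inverse-time law).

    Valid in the non-saturating regime where potency is governed by the
    product C * t; composing t1->t2->t3 equals t1->t3 by construction.
    """
    if ic50_ref <= 0 or t_ref <= 0 or t_new <= 0:
        raise ValidationError("ic50_ref, t_ref and t_new must all be > 0")
    return ic50_ref * t_ref / t_new


def fit_4pl_absolute_ic50(
    concs: Sequence[float],
    responses: Sequence[float],
    max_control: float,
    min_control: float,
) -> FourPLFit:
    """Four-parameter logistic fit with control-anchored absolute IC50.

    The absolute IC50 is the concentration where the *fitted* curve equals
    the midpoint of the control-defined signal window (max_control +
    min_control)/2, solved from the fitted parameters; when the fitted
    curve never reaches that midpoint within the tested range the result is
    flagged not determinable.
    """
    c = np.asarray(concs, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValidationError("concs and responses must be 1-D and equally long")
    if c.size < 5:
        raise ValidationError("need >= 5 concentration points")
    if np.any(c <= 0):
        raise ValidationError("concentrations must be > 0")
    if not max_control > min_control:
        raise ValidationError("max_control must exceed min_control")

    def fourpl(x, top, bottom, log_ic50, hill):
        return bottom + (top - bottom) / (1.0 + (x / np.exp(log_ic50)) ** hill)

    p0 = (float(r.max()), float(r.min()), float(np.log(np.median(c))), 1.0)
    try:
        with warnings.catch_warnings():
            # degenerate (flat) responses legitimately reach the
            # not-determinable branch; the covariance warning is noise there
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(fourpl, c, r, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ValidationError(f"4PL fit did not converge: {exc}") from None
    top, bottom, log_ic50, hill = (float(v) for v in popt)
    ic50_rel = math.exp(log_ic50)
    if top < bottom:
        top, bottom, hill = bottom, top, -hill

    midpoint = (max_control + min_control) / 2.0

    def fitted(x: float) -> float:
        return fourpl(x, *popt)

    lo, hi = float(c.min()) / 10.0, float(c.max()) * 10.0
    f_lo, f_hi = fitted(lo) - midpoint, fitted(hi) - midpoint
    if f_lo * f_hi > 0:
        return FourPLFit(top, bottom, None, abs(hill), ic50_rel, determinable=False)
    ic50_abs = float(brentq(lambda x: fitted(x) - midpoint, lo, hi, xtol=1e-12, rtol=1e-12))
    return FourPLFit(top, bottom, ic50_abs, abs(hill), ic50_rel, determinable=True)


def equivalent_invitro_concentration(
    occupancy_ss: float, model: CovalentAssayModel
) -> float:
    """Invert the assay model: the incubation concentration producing a
    given steady-state occupancy (percent).

    Closed form: with kobs_needed = -ln(1 - occ)/t, solve
    kinact*C/(KI + C) = kobs_needed, i.e. C = kobs_needed*KI /
    (kinact - kobs_needed).  Occupancies needing kobs >= kinact are
    unreachable at any concentration.
    """
    if not 0 <= occupancy_ss < 100:
        raise ValidationError(
            f"occupancy_ss must lie in [0, 100), got {occupancy_ss}"
        )
    occ = occupancy_ss / 100.0
    if occ == 0:
        return 0.0
    kobs_needed = -math.log1p(-occ) / model.incubation_time
    if kobs_needed >= model.kinact:
        raise ValidationError(
            f"occupancy {occupancy_ss}% requires kobs {kobs_needed:.3g}/h >= "
            f"kinact {model.kinact:.3g}/h: unreachable in this assay"
        )
    return kobs_needed * model.KI / (model.kinact - kobs_needed)


def pathway_inhibition_table(
    doses: Sequence[float],
    pk: PKParameters,
    turnover: TurnoverParameters,
    pathways: Mapping[str, EmaxModel],
    assay: CovalentAssayModel,
    interval: float = 24.0,
    n_doses: int = 28,
    occupancy_statistic: str = "average",
) -> pd.DataFrame:
    """Per-pathway inhibition across a clinical dose grid.

    For each dose the chain is: simulate repeated dosing to steady state,
    summarise occupancy over the final interval (``"average"`` or
    ``"trough"``), invert the in vitro assay to the equivalent incubation
    concentration (in the assay's nM units), and evaluate each
    pathway's Emax model at that concentration.  Returns a DataFrame
    indexed by dose with one column per pathway plus the intermediate
    occupancy and equivalent concentration.
    """
    if not pathways:
        raise ValidationError("pathways must be nonempty")
    if occupancy_statistic not in ("average", "trough"):
        raise ValidationError(f"unknown occupancy statistic {occupancy_statistic!r}")
    rows = []
    for dose in doses:
        if dose < 0:
            raise ValidationError("doses must be >= 0")
        if dose == 0:
            occ_ss = 0.0
        else:
            regimen = DosingRegimen(dose_amount=float(dose), n_doses=n_doses, interval=interval)
            t_end = regimen.last_dose_time + interval
            grid = np.linspace(0.0, t_end, int(t_end * 2) + 1)
            prof = simulate_occupancy(pk, turnover, regimen, grid)
            window = (regimen.last_dose_time, t_end)
            summ = occupancy_summary(prof, threshold=0.0, window=window)
            if occupancy_statistic == "trough":
                occ_ss = summ["min_occ"]
            else:
                mask = (grid >= window[0]) & (grid <= window[1])
                occ_ss = float(
                    np.trapezoid(prof.occupancy_pct[mask], grid[mask]) / interval
                )
        occ_ss = min(occ_ss, 99.999)  # numerical guard; 100% is uninvertible
        c_eq = equivalent_invitro_concentration(occ_ss, assay)
        row = {"dose_mg": float(dose), "occupancy_ss_pct": occ_ss, "c_eq_nM": c_eq}
        for name, emax_model in pathways.items():
            row[name] = float(emax_model.inhibition(c_eq))
        rows.append(row)
    return pd.DataFrame(rows).set_index("dose_mg")
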