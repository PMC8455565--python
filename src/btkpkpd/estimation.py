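"""Naive-pooled and two-stage parameter estimation with recovery tooling.

Fitting is deliberately simpler than a full nonlinear mixed-effects
analysis: a naive-pooled least-squares fit (all records of the supplied
dataset share one parameter vector — a single subject's records give an
individual fit) and a two-stage population summary (fit each subject, then
summarise geometric means and CVs).  Both are validated by
simulate-then-recover experiments rather than against external softwares.

Parameters are estimated on the log scale, which enforces positivity
without clipping; residuals are additive on log-concentration (close to a
proportional error model) for PK and additive on the free-target fraction
for occupancy fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import PKParameters, StudyDataset, TurnoverParameters, ValidationError
from .pk import simulate_pk_events
from .occupancy import simulate_occupancy_events

__all__ = [
    "FitResult",
    "fit_individual_pk",
    "fit_occupancy_params",
    "two_stage_summary",
]

PK_PARAM_NAMES = ("CL", "Vc", "Q", "Vp", "ktr", "F")

_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    objective: float
    se_approx: dict[str, float]
    converged: bool
    n_obs: int
    subject_id: str | None = None


def _subject_events_and_obs(
    dataset: StudyDataset, kind: str
) -> dict[str, tuple[list[tuple[float, float]], np.ndarray, np.ndarray]]:
    """Per-subject (dose events, observation times, observed values) for one
    record kind, excluding BLQ observations."""
    out = {}
    for sid in dataset.subjects():
        sub = dataset.for_subject(sid)
        events = [(r.time, r.value) for r in sub.of_kind("dose")]
        obs = [(r.time, r.value) for r in sub.of_kind(kind) if not r.blq_flag]
        if not obs:
            continue
        t_obs = np.array([t for t, _ in obs])
        v_obs = np.array([v for _, v in obs])
        out[sid] = (events, t_obs, v_obs)
    return out


def _sim_grid(events: Sequence[tuple[float, float]], t_obs: np.ndarray) -> np.ndarray:
    pts = np.concatenate([[0.0], [t for t, _ in events], t_obs])
    return np.unique(pts)


def _se_from_jacobian(res, names: Sequence[str], estimates: dict[str, float]) -> dict[str, float]:
    """Approximate natural-scale standard errors from the final Jacobian of
    the log-parameterised problem."""
    m, p = res.jac.shape
    if m <= p:
        return {n: math.nan for n in names}
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        s2 = 2 * res.cost / (m - p)
        se_log = np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0, None))
    except np.linalg.LinAlgError:
        return {n: math.nan for n in names}
    return {n: estimates[n] * float(se) for n, se in zip(names, se_log)}


def fit_individual_pk(
    dataset: StudyDataset,
    init: PKParameters,
    fixed: Iterable[str] = ("F",),
) -> FitResult:
    """Least-squares fit of the PK model on log-concentration residuals.

    ``fixed`` names the parameters held at their ``init`` value; ``F`` is
    fixed by default because oral data cannot separate bioavailability from
    clearance and volume.  BLQ observations are excluded.  The optimiser is
    a trust-region least-squares run on log-parameters; it is deterministic
    given the initial values.
    """
    fixed = set(fixed) | {"n_transit"}
    free_names = [n for n in PK_PARAM_NAMES if n not in fixed]
    if not free_names:
        raise ValidationError("no free parameters to estimate")
    per_subject = _subject_events_and_obs(dataset, "concentration")
    if not per_subject:
        raise ValidationError("no quantifiable concentration observations")
    n_obs = sum(v[2].size for v in per_subject.values())
    if n_obs < len(free_names):
        raise ValidationError(
            f"{n_obs} observations cannot support {len(free_names)} free parameters"
        )
    grids = {
        sid: _sim_grid(events, t_obs)
        for sid, (events, t_obs, _) in per_subject.items()
    }

    def build(theta_log: np.ndarray) -> PKParameters:
        updates = {n: math.exp(v) for n, v in zip(free_names, theta_log)}
        if "F" in updates:
            updates["F"] = min(updates["F"], 1.0)
        return replace(init, **updates)

    def residuals(theta_log: np.ndarray) -> np.ndarray:
        params = build(theta_log)
        res = []
        for sid, (events, t_obs, v_obs) in per_subject.items():
            prof = simulate_pk_events(params, events, grids[sid])
            pred = np.maximum(np.interp(t_obs, prof.times, prof.central_conc), _LOG_FLOOR)
            res.append(np.log(pred) - np.log(np.maximum(v_obs, _LOG_FLOOR)))
        return np.concatenate(res)

    x0 = np.array([math.log(getattr(init, n)) for n in free_names])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-10, ftol=1e-10)
    params_hat = build(sol.x)
    estimates = {n: getattr(params_hat, n) for n in free_names}
    return FitResult(
        estimates=estimates,
        objective=float(2 * sol.cost),
        se_approx=_se_from_jacobian(sol, free_names, estimates),
        converged=bool(sol.success),
        n_obs=n_obs,
    )


def fit_occupancy_params(
    dataset: StudyDataset,
    pk_fixed: PKParameters,
    init: TurnoverParameters,
) -> FitResult:
    """Sequential PK->PD fit of the turnover parameters kdeg and kbind.

    PK parameters are fixed (sequential fitting); free-target observations
    are modelled as the fraction of baseline, so ksyn is tied to the
    baseline normalisation (ksyn = kdeg * baseline) and only kdeg and
    kbind are estimated, by least squares on the free fraction.
    """
    per_subject = _subject_events_and_obs(dataset, "free_btk")
    if not per_subject:
        raise ValidationError("dataset has no free_btk observations")
    n_obs = sum(v[2].size for v in per_subject.values())
    baseline = init.baseline if init.kdeg > 0 else 1.0
    grids = {
        sid: _sim_grid(events, t_obs)
        for sid, (events, t_obs, _) in per_subject.items()
    }
    names = ["kdeg", "kbind"]

    def build(theta_log: np.ndarray) -> TurnoverParameters:
        kdeg, kbind = (math.exp(v) for v in theta_log)
        return TurnoverParameters(ksyn=kdeg * baseline, kdeg=kdeg, kbind=kbind)

    def residuals(theta_log: np.ndarray) -> np.ndarray:
        turn = build(theta_log)
        res = []
        for sid, (events, t_obs, v_obs) in per_subject.items():
            prof = simulate_occupancy_events(pk_fixed, turn, events, grids[sid])
            pred = np.interp(t_obs, prof.times, prof.free_fraction())
            res.append(pred - v_obs / baseline)
        return np.concatenate(res)

    x0 = np.array([math.log(max(init.kdeg, 1e-6)), math.log(max(init.kbind, 1e-9))])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-10, ftol=1e-10)
    turn_hat = build(sol.x)
    estimates = {"kdeg": turn_hat.kdeg, "kbind": turn_hat.kbind, "ksyn": turn_hat.ksyn}
    return FitResult(
        estimates=estimates,
        objective=float(2 * sol.cost),
        se_approx=_se_from_jacobian(sol, names, estimates),
        converged=bool(sol.success),
        n_obs=n_obs,
    )


def two_stage_summary(fits: Sequence[FitResult]) -> dict[str, dict[str, float]]:
    """Geometric mean and geometric CV of each parameter across subjects.

    Non-converged fits are excluded with a warning; at least two converged
    fits are required.  The geometric CV is sqrt(exp(var(log)) - 1), the
    natural summary when inter-subject variability is log-normal.
    """
    converged = [f for f in fits if f.converged]
    n_dropped = len(fits) - len(converged)
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} non-converged fit(s)", stacklevel=2)
    if len(converged) < 2:
        raise ValidationError("need >= 2 converged fits")
    names = sorted(set().union(*(f.estimates for f in converged)))
    out: dict[str, dict[str, float]] = {}
    for name in names:
        vals = np.array(
            [f.estimates[name] for f in converged if name in f.estimates]
        )
        logs = np.log(np.maximum(vals, _LOG_FLOOR))
        var = float(np.var(logs, ddof=1))
        out[name] = {
            "geo_mean": float(np.exp(np.mean(logs))),
            "cv": float(math.sqrt(math.expm1(var))),
            "n": int(vals.size),
        }
    return out
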