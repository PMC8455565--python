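"""Two-compartment oral PK with a transit-compartment absorption chain.

The model states are, in order: ``n_abs`` absorption/transit compartments
(amount, mg), central amount (mg), peripheral amount (mg), and a cumulative
eliminated-mass accumulator used for mass-balance checks.  Each oral dose
deposits ``F * amount`` into the first transit compartment at the event
time; the solver restarts at every event so the discontinuity is handled
exactly rather than smoothed.

All dynamics are linear, so superposition of time-shifted single-dose
profiles is an independent oracle for any multiple-dose simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import DosingRegimen, PKParameters, ValidationError, expand_regimen

__all__ = [
    "ConcentrationProfile",
    "IntegrationError",
    "simulate_pk",
    "simulate_pk_events",
    "superposition_profile",
    "steady_state_metrics",
]

MG_PER_L_TO_NG_PER_ML = 1000.0  # 1 mg/L = 1 ug/mL = 1000 ng/mL

RTOL = 1e-10
ATOL = 1e-12


class IntegrationError(RuntimeError):
    """The ODE solver failed to converge; the message carries diagnostics."""


@dataclass
class ConcentrationProfile:
    """Simulated concentration-time profile with full state trajectories."""

    times: np.ndarray          # h, strictly increasing
    central_conc: np.ndarray   # ng/mL
    state: np.ndarray          # (n_times, n_states) amounts, mg
    state_labels: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.central_conc = np.asarray(self.central_conc, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("profile times must be strictly increasing")

    def conc_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of the central concentration."""
        return np.interp(t, self.times, self.central_conc)

    @property
    def eliminated(self) -> np.ndarray:
        return self.state[:, -1]


def n_abs_compartments(params: PKParameters) -> int:
    # n_transit = 0 collapses to a single first-order depot with rate ktr
    return max(params.n_transit, 1)


def pk_state_labels(params: PKParameters) -> list[str]:
    n_abs = n_abs_compartments(params)
    return [f"transit_{i + 1}" for i in range(n_abs)] + [
        "central",
        "peripheral",
        "eliminated",
    ]


def pk_rhs(params: PKParameters) -> Callable[[float, np.ndarray], np.ndarray]:
    """Right-hand side of the linear PK ODE system."""
    n_abs = n_abs_compartments(params)
    ktr = params.ktr
    kel = params.CL / params.Vc
    k12 = params.Q / params.Vc if params.Q > 0 else 0.0
    k21 = params.Q / params.Vp if params.Vp > 0 else 0.0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        dy[0] = -ktr * y[0]
        for i in range(1, n_abs):
            dy[i] = ktr * (y[i - 1] - y[i])
        ac, ap = y[n_abs], y[n_abs + 1]
        dy[n_abs] = ktr * y[n_abs - 1] - kel * ac - k12 * ac + k21 * ap
        dy[n_abs + 1] = k12 * ac - k21 * ap
        dy[n_abs + 2] = kel * ac
        return dy

    return rhs


def integrate_with_doses(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    dose_events: Sequence[tuple[float, float]],
    grid: np.ndarray,
    depot_index: int = 0,
) -> np.ndarray:
    """Integrate ``rhs`` over ``grid``, adding dose amounts to the depot
    state at each event time with a solver restart.

    Grid points that coincide with an event report the post-dose state.
    Returns an array of shape ``(len(grid), len(y0))``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be 1-D and strictly increasing")
    events = sorted((float(t), float(a)) for t, a in dose_events if a != 0)
    if events and events[0][0] < grid[0] - 1e-12:
        raise ValidationError("grid must start at or before the first dose event")

    t_start, t_end = grid[0], grid[-1]
    y = np.array(y0, dtype=float)

    def doses_at(t: float) -> float:
        return sum(a for te, a in events if abs(te - t) <= 1e-12)

    # segment breakpoints: start, interior event times, end
    interior = sorted({te for te, _ in events if t_start + 1e-12 < te < t_end - 1e-12})
    breaks = [t_start] + interior + [t_end]

    out = np.empty((grid.size, y.size))
    y[depot_index] += doses_at(t_start)
    out[0] = y
    filled = 1
    for t_a, t_b in zip(breaks[:-1], breaks[1:]):
        t_eval = grid[(grid > t_a + 1e-12) & (grid <= t_b + 1e-12)]
        needs_end = t_eval.size == 0 or abs(t_eval[-1] - t_b) > 1e-12
        t_span_eval = np.append(t_eval, t_b) if needs_end else t_eval
        sol = solve_ivp(
            rhs,
            (t_a, t_b),
            y,
            method="LSODA",
            t_eval=t_span_eval,
            rtol=RTOL,
            atol=ATOL,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed on [{t_a}, {t_b}]: {sol.message}"
            )
        n_rec = t_eval.size
        if n_rec:
            out[filled : filled + n_rec] = sol.y[:, :n_rec].T
            filled += n_rec
        y = np.array(sol.y[:, -1], dtype=float)
        bolus = doses_at(t_b)
        if bolus:
            y[depot_index] += bolus
            if n_rec and abs(grid[filled - 1] - t_b) <= 1e-12:
                out[filled - 1] = y  # grid point at an event: post-dose state
    if filled != grid.size:
        raise IntegrationError("grid not fully covered by integration")
    return out


def simulate_pk_events(
    params: PKParameters,
    dose_events: Sequence[tuple[float, float]],
    grid: np.ndarray,
) -> ConcentrationProfile:
    """Simulate the PK model for explicit ``(time, amount)`` oral dose events."""
    n_abs = n_abs_compartments(params)
    labels = pk_state_labels(params)
    y0 = np.zeros(n_abs + 3)
    scaled = [(t, params.F * amt) for t, amt in dose_events]
    states = integrate_with_doses(pk_rhs(params), y0, scaled, np.asarray(grid, float))
    conc = states[:, n_abs] / params.Vc * MG_PER_L_TO_NG_PER_ML
    return ConcentrationProfile(
        times=np.asarray(grid, float),
        central_conc=conc,
        state=states,
        state_labels=labels,
    )


def simulate_pk(
    params: PKParameters,
    regimen: DosingRegimen | None,
    grid: np.ndarray,
) -> ConcentrationProfile:
    """Simulate the PK model under a dosing regimen on the given time grid.

    ``regimen=None`` (or a zero-event list) yields the trivial all-zero
    profile.  The grid must start at or before the first dose.
    """
    events = expand_regimen(regimen) if regimen is not None else []
    return simulate_pk_events(params, events, grid)


def superposition_profile(
    params: PKParameters,
    regimen: DosingRegimen,
    single_dose_profile: ConcentrationProfile,
) -> ConcentrationProfile:
    """Multiple-dose profile by superposition of a single-dose profile.

    Valid for linear PK only; serves as an independent cross-check of the
    ODE route.  The single-dose profile must have been simulated for one
    dose of the regimen's amount given at its own ``times[0]``; times
    outside the profile range contribute zero (the profile should span the
    washout of interest).  Output is on the single-dose grid.
    """
    t0 = single_dose_profile.times[0]
    rel_t = single_dose_profile.times - t0
    rel_c = single_dose_profile.central_conc
    grid = single_dose_profile.times
    total = np.zeros_like(grid)
    for t_dose, _amt in expand_regimen(regimen):
        shifted = grid - t_dose
        mask = shifted >= 0
        total[mask] += np.interp(shifted[mask], rel_t, rel_c, left=0.0, right=0.0)
    return ConcentrationProfile(
        times=grid,
        central_conc=total,
        state=np.zeros((grid.size, 0)),
        state_labels=[],
    )


def steady_state_metrics(
    profile: ConcentrationProfile,
    interval: float,
    last_dose_time: float,
) -> dict[str, float]:
    """Cmax, Cmin and AUC over one dosing interval after the last dose.

    Values are computed on ``[last_dose_time, last_dose_time + interval]``
    with the window endpoints interpolated onto the profile; AUC uses the
    linear trapezoid.
    """
    t_lo, t_hi = last_dose_time, last_dose_time + interval
    if t_lo < profile.times[0] - 1e-9 or t_hi > profile.times[-1] + 1e-9:
        raise ValidationError(
            f"profile [{profile.times[0]}, {profile.times[-1]}] does not cover "
            f"the dosing interval [{t_lo}, {t_hi}]"
        )
    inner = (profile.times > t_lo) & (profile.times < t_hi)
    t_win = np.concatenate(([t_lo], profile.times[inner], [t_hi]))
    c_win = np.concatenate(
        ([float(profile.conc_at(t_lo))], profile.central_conc[inner], [float(profile.conc_at(t_hi))])
    )
    return {
        "Cmax_ss": float(np.max(c_win)),
        "Cmin_ss": float(np.min(c_win)),
        "AUC_tau": float(np.trapezoid(c_win, t_win)),
    }
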