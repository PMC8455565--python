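"""Synthetic study generators shaped like the source study designs.

Three generators produce long-format datasets for the rest of the package:

* a rat collagen-induced-arthritis (CIA) PK/PD study — 0.3/1/3 mg/kg oral
  once daily for 9 days (n = 20 per treated arm, n = 8 vehicle controls),
  plasma sampled after the final dose and censored at an LLOQ of
  0.5 ng/mL, with probe-ELISA free-target measurements at 0/4/12/24 h
  after the last dose;
* a human multiple-ascending-dose study — twice-daily 5/20/40/60 mg arms
  dosed for 14 days, sampled at 0/1/2/4/8/12/24/48/120 h, with both
  plasma concentrations and free-target fractions;
* paired efficacy-score / PD-marker samples with a chosen correlation on
  a 0-16 arthritis-score scale.

Inter-subject variability is log-normal on the positive parameters;
residual error on concentration is combined proportional + additive, and
free-target fractions get additive assay noise clipped to [0, 1.2] (free
signal can exceed total in a real ELISA).  Every generator is
deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DosingRegimen,
    ObservationRecord,
    PKParameters,
    StudyDataset,
    TurnoverParameters,
    ValidationError,
    expand_regimen,
)
from .occupancy import simulate_occupancy_events

__all__ = [
    "ResidualError",
    "PopulationSpec",
    "StudyDesign",
    "default_human_mad_design",
    "generate_human_study",
    "generate_rat_cia_study",
    "generate_pd_efficacy_pairs",
    "RAT_BODY_WEIGHT_KG",
]

RAT_BODY_WEIGHT_KG = 0.15        # 150 g animals
RAT_CIA_DOSES_MG_PER_KG = (0.3, 1.0, 3.0)
RAT_CIA_N_PER_ARM = 20
RAT_CIA_N_CONTROL = 8
RAT_CIA_DOSING_DAYS = 9
RAT_PD_OFFSETS_H = (0.0, 4.0, 12.0, 24.0)           # after the final dose
# The study reports NCA exposure metrics but not the PK sampling times that
# produced them; a standard small-animal serial-bleed schedule is used.
RAT_PK_OFFSETS_H = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)

HUMAN_BID_DOSES_MG = (5.0, 20.0, 40.0, 60.0)
HUMAN_MAD_DAYS = 14
HUMAN_SAMPLING_H = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0, 120.0)
DEFAULT_LLOQ = 0.5  # ng/mL


@dataclass(frozen=True)
class ResidualError:
    proportional_sd: float = 0.10
    additive_sd: float = 0.05  # ng/mL

    def __post_init__(self) -> None:
        if self.proportional_sd < 0 or self.additive_sd < 0:
            raise ValidationError("residual SDs must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Typical parameters plus the stochastic structure of a population."""

    typical_pk: PKParameters
    typical_turnover: TurnoverParameters
    iiv_omegas: Mapping[str, float] = field(
        default_factory=lambda: {"CL": 0.3, "Vc": 0.3, "ktr": 0.3}
    )
    residual: ResidualError = ResidualError()
    seed: int = 0

    def __post_init__(self) -> None:
        for name, om in self.iiv_omegas.items():
            if om < 0:
                raise ValidationError(f"omega for {name} must be >= 0")

    @classmethod
    def default_human(cls, seed: int = 0) -> "PopulationSpec":
        return cls(
            typical_pk=PKParameters.default_human(),
            typical_turnover=TurnoverParameters.default_human(),
            seed=seed,
        )

    @classmethod
    def default_rat(cls, seed: int = 0) -> "PopulationSpec":
        return cls(
            typical_pk=PKParameters.default_rat(),
            typical_turnover=TurnoverParameters.default_human(),
            seed=seed,
        )


@dataclass(frozen=True)
class StudyDesign:
    """Arms (regimen + group size), per-arm sampling times, and assay limits."""

    arms: tuple[tuple[DosingRegimen, int], ...]
    sampling_times: tuple[tuple[float, ...], ...]
    lloq: float = DEFAULT_LLOQ
    assay_noise_btk: float = 0.05  # additive SD on the free fraction

    def __post_init__(self) -> None:
        if len(self.arms) != len(self.sampling_times):
            raise ValidationError("one sampling-time list is required per arm")
        if self.lloq <= 0:
            raise ValidationError("lloq must be > 0")
        for (_, n), times in zip(self.arms, self.sampling_times):
            if n < 1:
                raise ValidationError("each arm needs >= 1 subject")
            if any(t < 0 for t in times) or list(times) != sorted(times):
                raise ValidationError("sampling times must be >= 0 and sorted")


def default_human_mad_design(
    doses: Sequence[float] = HUMAN_BID_DOSES_MG,
    n_per_arm: int = 6,
    lloq: float = DEFAULT_LLOQ,
) -> StudyDesign:
    """Twice-daily multiple-dose design: 14 days of BID dosing per arm."""
    arms = tuple(
        (DosingRegimen(dose_amount=d, n_doses=2 * HUMAN_MAD_DAYS, interval=12.0), n_per_arm)
        for d in doses
    )
    sampling = tuple(HUMAN_SAMPLING_H for _ in doses)
    return StudyDesign(arms=arms, sampling_times=sampling, lloq=lloq)


def _sample_individual_pk(
    rng: np.random.Generator, pop: PopulationSpec
) -> tuple[PKParameters, TurnoverParameters]:
    pk_updates: dict[str, float] = {}
    to_updates: dict[str, float] = {}
    for name, omega in pop.iiv_omegas.items():
        eta = rng.normal(0.0, omega) if omega > 0 else 0.0
        if hasattr(pop.typical_pk, name):
            val = getattr(pop.typical_pk, name) * math.exp(eta)
            if name == "F":
                val = min(val, 1.0)
            pk_updates[name] = val
        elif hasattr(pop.typical_turnover, name):
            to_updates[name] = getattr(pop.typical_turnover, name) * math.exp(eta)
        else:
            raise ValidationError(f"unknown parameter {name!r} in iiv_omegas")
    pk = replace(pop.typical_pk, **pk_updates) if pk_updates else pop.typical_pk
    to = replace(pop.typical_turnover, **to_updates) if to_updates else pop.typical_turnover
    return pk, to


def _observe_concentration(
    rng: np.random.Generator, true_conc: np.ndarray, residual: ResidualError
) -> np.ndarray:
    eps_p = rng.normal(0.0, residual.proportional_sd, size=true_conc.shape)
    eps_a = rng.normal(0.0, residual.additive_sd, size=true_conc.shape)
    return np.clip(true_conc * (1.0 + eps_p) + eps_a, 0.0, None)


def _observe_free_fraction(
    rng: np.random.Generator, true_frac: np.ndarray, sd: float
) -> np.ndarray:
    noisy = true_frac + rng.normal(0.0, sd, size=true_frac.shape)
    return np.clip(noisy, 0.0, 1.2)


def _subject_records(
    rng: np.random.Generator,
    sid: str,
    group: str,
    pop: PopulationSpec,
    events: list[tuple[float, float]],
    conc_times: np.ndarray,
    btk_times: np.ndarray | None,
    lloq: float,
    assay_noise_btk: float,
) -> list[ObservationRecord]:
    pk_i, to_i = _sample_individual_pk(rng, pop)
    all_times = np.unique(
        np.concatenate(
            [[0.0], [t for t, _ in events], conc_times, btk_times if btk_times is not None else []]
        )
    )
    records: list[ObservationRecord] = [
        ObservationRecord(sid, t, "dose", amt, dose_group=group) for t, amt in events
    ]
    if events:
        prof = simulate_occupancy_events(pk_i, to_i, events, all_times)
        conc_true = np.interp(conc_times, prof.times, prof.central_conc)
        free_true = (
            np.interp(btk_times, prof.times, prof.free_fraction())
            if btk_times is not None
            else None
        )
    else:
        conc_true = np.zeros_like(conc_times)
        free_true = np.ones_like(btk_times) if btk_times is not None else None

    conc_obs = _observe_concentration(rng, conc_true, pop.residual)
    for t, v in zip(conc_times, conc_obs):
        records.append(
            ObservationRecord(
                sid, float(t), "concentration", float(v), blq_flag=bool(v < lloq), dose_group=group
            )
        )
    if btk_times is not None and free_true is not None:
        free_obs = _observe_free_fraction(rng, free_true, assay_noise_btk)
        records.append(ObservationRecord(sid, 0.0, "total_btk", 1.0, dose_group=group))
        for t, v in zip(btk_times, free_obs):
            records.append(
                ObservationRecord(sid, float(t), "free_btk", float(v), dose_group=group)
            )
    return records


def generate_human_study(
    pop: PopulationSpec,
    design: StudyDesign | None = None,
    seed: int | None = None,
) -> StudyDataset:
    """Simulate a multiple-ascending-dose study with PK and free-target PD.

    Individual parameters are drawn log-normally around the typical values,
    the coupled PK/occupancy system is simulated per subject, residual and
    assay noise applied, and concentrations below the LLOQ flagged.
    """
    design = design or default_human_mad_design()
    rng = np.random.default_rng(pop.seed if seed is None else seed)
    records: list[ObservationRecord] = []
    subj = 0
    for (regimen, n), times in zip(design.arms, design.sampling_times):
        group = f"{regimen.dose_amount:g}mg"
        events = expand_regimen(regimen)
        t_arr = np.asarray(times, dtype=float)
        for _ in range(n):
            subj += 1
            records.extend(
                _subject_records(
                    rng,
                    f"S{subj:03d}",
                    group,
                    pop,
                    events,
                    conc_times=t_arr,
                    btk_times=t_arr,
                    lloq=design.lloq,
                    assay_noise_btk=design.assay_noise_btk,
                )
            )
    return StudyDataset(records=records, lloq=design.lloq)


def generate_rat_cia_study(
    pop: PopulationSpec,
    doses_mg_per_kg: Sequence[float] = RAT_CIA_DOSES_MG_PER_KG,
    n_per_arm: int = RAT_CIA_N_PER_ARM,
    n_control: int = RAT_CIA_N_CONTROL,
    body_weight_kg: float = RAT_BODY_WEIGHT_KG,
    f_dose_exponent: float = 0.0,
    pk_offsets_h: Sequence[float] = RAT_PK_OFFSETS_H,
    pd_offsets_h: Sequence[float] = RAT_PD_OFFSETS_H,
    lloq: float = DEFAULT_LLOQ,
    assay_noise_btk: float = 0.05,
    seed: int | None = None,
) -> StudyDataset:
    """Simulate the rat arthritis PK/PD study: 9-day once-daily oral dosing
    with terminal PK and PD sampling after the final dose.

    ``f_dose_exponent`` is the supra-proportional exposure hook: effective
    bioavailability scales as (dose / 1 mg/kg)**exponent, so AUC grows as
    dose**(1 + exponent).  An exponent near 0.5 emulates the observed
    greater-than-proportional exposure; the default 0 keeps PK linear.
    A zero-dose arm (vehicle controls) contributes BLQ concentrations and
    unbound target only.
    """
    rng = np.random.default_rng(pop.seed if seed is None else seed)
    records: list[ObservationRecord] = []
    t_last = (RAT_CIA_DOSING_DAYS - 1) * 24.0
    subj = 0
    arms = [(0.0, n_control)] + [(float(d), n_per_arm) for d in doses_mg_per_kg]
    for dose_mgkg, n in arms:
        group = f"{dose_mgkg:g}mgkg" if dose_mgkg > 0 else "control"
        if dose_mgkg > 0:
            f_scale = (dose_mgkg / 1.0) ** f_dose_exponent
            pop_arm = replace(
                pop,
                typical_pk=replace(
                    pop.typical_pk, F=min(pop.typical_pk.F * f_scale, 1.0)
                ),
            )
            amount_mg = dose_mgkg * body_weight_kg
            regimen = DosingRegimen(
                dose_amount=amount_mg, n_doses=RAT_CIA_DOSING_DAYS, interval=24.0
            )
            events = expand_regimen(regimen)
        else:
            pop_arm = pop
            events = []
        conc_times = np.asarray([t_last + o for o in pk_offsets_h])
        btk_times = np.asarray([t_last + o for o in pd_offsets_h])
        for _ in range(n):
            subj += 1
            records.extend(
                _subject_records(
                    rng,
                    f"R{subj:03d}",
                    group,
                    pop_arm,
                    events,
                    conc_times=conc_times,
                    btk_times=btk_times,
                    lloq=lloq,
                    assay_noise_btk=assay_noise_btk,
                )
            )
    return StudyDataset(records=records, lloq=lloq)


def generate_pd_efficacy_pairs(
    n: int,
    target_r: float,
    score_range: tuple[float, float] = (0.0, 16.0),
    seed: int = 0,
    marker_range: tuple[float, float] = (0.0, 100.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (arthritis score, PD marker) samples with a target Pearson
    correlation.

    Pairs are bivariate normal with correlation ``target_r``, centred in
    their ranges with a +/-3 sigma span, then clipped; |target_r| = 1
    yields exactly collinear pairs.  Returns (scores, markers).
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValidationError(f"target_r must lie in [-1, 1], got {target_r}")
    if n < 3:
        raise ValidationError("need n >= 3 pairs")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    if abs(target_r) == 1.0:
        z2 = math.copysign(1.0, target_r) * z1
    else:
        z2 = target_r * z1 + math.sqrt(1.0 - target_r**2) * rng.standard_normal(n)

    def to_range(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
        centre, sd = (lo + hi) / 2.0, (hi - lo) / 6.0
        return np.clip(centre + sd * z, lo, hi)

    scores = to_range(z1, *score_range)
    markers = to_range(z2, *marker_range)
    return scores, markers
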