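# Methods

This note records the modeling assumptions, parameter choices, numerical
settings, and known limitations of `btkpkpd`, in the spirit of a model
description accompanying a pharmacometric analysis.

## Units and data conventions

Time is in hours, dose amounts in mg, plasma concentration in ng/mL
(1 mg/L = 1000 ng/mL), and target amounts in arbitrary units normalised so
that only the free/total ratio is meaningful. Molar conversion
(ng/mL → nM via the molecular weight, 470.52 g/mol for the reference
compound) is exposed as a single explicit function and used only at the in
vitro bridging boundary, where assay potencies are molar.

Datasets are long-format CSV in the style of NONMEM-type software: one row
per dose event or observation with columns `id,time,kind,amt,dv,blq,group`
(`evid` accepted in place of `kind`; `.` is a missing value). Observations
below the lower limit of quantification (LLOQ, default 0.5 ng/mL) are
retained and flagged rather than dropped, because downstream consumers need
different censoring policies: NCA treats pre-Tmax BLQ as zero and excludes
post-Tmax BLQ, while least-squares estimation excludes BLQ entirely.

## PK model

Two-compartment disposition (CL, Vc, Q, Vp) with oral input through a chain
of `n_transit` transit compartments at rate `ktr`; `n_transit = 0` collapses
to a single first-order depot. Each oral dose deposits `F × amount` into
the first transit compartment at the event time. The transit chain produces
the gamma-shaped, delayed absorption flux that a lag-time model would
approximate discontinuously; no separate lag parameter is used, and
observed absorption-peak times in the 1–2 h range are matched through
`ktr` alone.

Integration uses LSODA with `rtol 1e-10 / atol 1e-12` and an exact restart
at every dose event (no impulse smoothing). The tight tolerances are
deliberate: two independent solves must agree to ~1e-8 so that linearity
and superposition can be asserted at that level in the tests. A cumulative
eliminated-mass state is carried alongside the compartments, making total
mass conservation (`compartments + eliminated = administered`) a direct
solver check. For linear PK, superposition of time-shifted single-dose
solutions is an independent oracle for any multiple-dose profile; the
comparison is exact on grids whose spacing divides the dosing interval
(otherwise linear resampling adds its own interpolation error).

## Target-occupancy model

Free target follows turnover kinetics — zero-order synthesis `ksyn`,
first-order degradation `kdeg` — and is irreversibly inactivated by drug at
a second-order rate `kbind · C(t)` in plasma-concentration units. Bound
target is cleared at the same rate as free target. Two consequences are
used as structural checks:

* **Conservation**: free + bound equals the baseline `ksyn/kdeg` at all
  times, exactly.
* **Hyperbolic steady state**: under constant concentration, occupancy
  approaches `100 · kbind·C / (kdeg + kbind·C)`, with half-saturation at
  `C = kdeg/kbind`.

Occupancy is reported post hoc as `100 − free/total × 100` with baseline
free standing in for total — the convention of probe-ELISA occupancy
assays, where the pre-dose free signal defines 100% available target.
Instantaneous free + bound is also available but is not the default. Values
are clipped to [0, 100]; a free signal above total (possible with assay
noise) clips to 0% with a warning.

No reversible-complex step precedes inactivation in vivo: binding is pure
second-order, which is the identifiable form when only free-target
fractions are observed. The saturating kinact/KI form lives in the
bridging module, where in vitro concentration-response data can support it.

The model's defining qualitative behaviour — occupancy persisting long
after plasma concentrations fall below the LLOQ, because recovery requires
resynthesis at rate `kdeg` — emerges structurally: on washout, occupancy
decays log-linearly with slope `−kdeg`, independent of the PK.

## Default parameter values

No fitted PK or turnover estimates are published for the reference
compound, so the package ships *illustrative* defaults, chosen once to
reproduce the qualitative behaviours reported for this class and clearly
labeled as such:

| parameter | human | rat | rationale |
|---|---|---|---|
| CL (L/h) | 60 | 1.5 | high apparent oral clearance, low ng/mL exposures |
| Vc (L) | 100 | 0.8 | moderate central volume |
| Q (L/h) | 20 | 0.4 | biphasic decline, terminal t½ ≈ 10 h (human) |
| Vp (L) | 200 | 2.0 | |
| ktr (1/h) | 8 | 6 | absorption peak 1–2 h with n_transit = 3 |
| F | 0.3 | 0.1 | low oral bioavailability |
| ksyn = kdeg (1/h) | 0.01 | 0.01 | target half-life ≈ 3 days, baseline 1.0 |
| kbind ((ng/mL)·h)⁻¹ | 0.02 | 0.02 | near-saturating occupancy within hours at tens of ng/mL |

`n_transit` defaults to 3; the count is arbitrary (any small n gives the
same qualitative delay) and estimable in principle. The rat defaults put a
1 mg/kg × 0.15 kg dose at an AUC of order 10 ng·h/mL, the magnitude of the
published group means.

## NCA and dose-proportionality statistics

AUClast uses the linear trapezoid by default so worked examples are
hand-checkable; lin-up/log-down is available. λz comes from a log-linear
regression on the last 3 quantifiable points (never including Tmax), with
adjusted R² reported; AUCinf = AUClast + Clast/λz. Dose-group ratio tables
divide each group mean by the lowest-dose group mean and round half-up to
one decimal — the convention under which 49.9/2.0 = 24.95 prints as 25.0.

The power model is ordinary least squares of ln(exposure) on ln(dose); the
90% CI of the slope uses the t distribution with n−2 df. The acceptance
interval derives from bioequivalence limits (θL, θU) and the study dose
ratio r as `(1 + ln θL/ln r, 1 + ln θU/ln r)`. The default limits
(0.80, 1.25) are the standard bioequivalence pair and the only pair that
yields the conventional 0.90–1.10 band at a 10-fold dose range. Verdicts:
*proportional* if the CI lies inside the band, *nonproportional* if
disjoint from it, otherwise *inconclusive*. Note that a slope fitted to
three group means has only 1 residual df; per-subject data is the intended
input, and group-mean fits are for arithmetic cross-checks.

## Estimation

Full nonlinear mixed-effects estimation is out of scope; the package
provides a naive-pooled least-squares fit and a two-stage population
summary, validated by simulate-then-recover experiments. Residuals are
additive on log-concentration for PK (≈ proportional error, matching the
generator's default) and additive on the free-target fraction for PD.
Parameters are estimated on the log scale — positivity by construction,
no clipping — with a Levenberg–Marquardt least-squares run
(`xtol = ftol = 1e-10`), deterministic given the data and initial values.
Standard errors are approximated from the final Jacobian.

Identifiability dictates the defaults: oral data cannot separate F from
CL and Vc, so F is always fixed; the sequential PK→PD fit holds PK fixed
and estimates (kdeg, kbind) with ksyn tied to the baseline normalisation.
In the two-stage summary, inter-subject spread is reported as geometric
mean and geometric CV (`sqrt(exp(var log) − 1)`); recovery of a generating
ω is asserted for clearance, the parameter a single-profile design
identifies best — sparse individual fits inflate the apparent variability
of absorption and volume parameters, a known two-stage bias that the
summary does not correct.

## Bridging layer

In vitro covalent potency follows `kobs = kinact·C/(KI + C)` over the
incubation time t, giving occupancy `1 − exp(−kobs t)`. In the
non-saturating regime the apparent IC50 satisfies `C·t = ln2·KI/kinact`,
hence the inverse-time rescaling of covalent IC50s between incubation
times; the saturating form is used whenever KI is supplied. Absolute IC50s
are read from a least-squares 4-parameter-logistic fit at the midpoint of
the control-defined signal window, with a not-determinable flag when the
fitted curve never crosses that midpoint.

Dose projection chains: simulate repeated dosing to steady state (28 daily
doses by default), summarise occupancy over the last interval (average by
default; trough available — the published analyses do not state which was
matched), invert the assay model in closed form to an equivalent in vitro
concentration, and evaluate each pathway's sigmoid-Emax model there.
Pathway Emax/EC50 values are configuration, not constants, because the
underlying assay table is not published in full. The downstream
virtual-population disease model that would turn pathway inhibition into
clinical response scores is intentionally not reimplemented; the bridging
layer stops at the per-pathway inhibition table, which is the part that is
specified mechanistically.

## Synthetic data

The generators emulate the two study shapes end to end. Inter-subject
variability is log-normal on positive parameters (ω defaults: 0.3 on CL,
Vc, ktr); residual error on concentration is combined proportional (10%) +
additive (0.05 ng/mL); free-target fractions get additive assay noise
(SD 0.05) clipped to [0, 1.2], since free can exceed total in a real
ELISA. Concentrations below the LLOQ are flagged, not removed. All draws
come from a single `numpy` generator seeded per call: identical seeds give
identical datasets.

Rat study specifics: 9 once-daily doses at 0.3/1/3 mg/kg (converted to mg
with a configurable 0.15 kg body weight), n = 20 per treated arm and 8
vehicle controls, PD sampling at 0/4/12/24 h after the final dose. The
source study reports NCA exposure metrics without stating the PK sampling
times that produced them — at the PD times alone, plasma is below the
LLOQ beyond 4 h and NCA would be impossible — so the generator uses a
standard small-animal serial-bleed schedule (0.25–24 h post last dose) for
concentrations and keeps the sparse schedule for the PD observations.
Supra-proportional exposure is emulated by an optional hook that scales
bioavailability as `(dose / 1 mg/kg)^γ` (off by default; γ ≈ 0.5
reproduces a power-model slope well above the acceptance band). The hook is
a phenomenological stand-in: the mechanism behind the observed
nonproportionality (saturable first-pass, solubility) is not identified in
the source data.

Human study specifics: twice-daily arms of 5/20/40/60 mg for 14 days,
n = 6 per arm, sampling at 0/1/2/4/8/12/24/48/120 h, with both plasma
concentrations and free-target fractions per subject.

What the generators do *not* emulate: between-occasion variability,
covariate effects (weight, food), dropout, assay batch effects, disease
progression in the arthritis score, and any tissue compartment for the
target. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to real-data
pathologies.

PD-efficacy pairs are bivariate normal with a chosen correlation, mapped
to the 0–16 arthritis-score scale (centre of range, ±3σ span) and clipped;
clipping slightly attenuates extreme correlations, which the recovery
tolerance accounts for.

## Problem sizes and numerical choices

Simulations in the test suite and acceptance script use: dense grids of
200–2000 points over 2–14 simulated days; 20 random parameter draws for
the conservation property; 40 subjects for the two-stage experiment; 8
animals per arm for the end-to-end dose-proportionality pipeline; and
single-subject fits on 12-point rich designs (PK) and the 9-point clinical
schedule (PD). These sizes keep every stochastic check reproducible in
seconds while leaving the estimators genuinely nontrivial work.

Ties and degenerate inputs: Cmax takes the first grid time at the maximum;
threshold-crossing times in occupancy summaries are linearly interpolated;
λz is flagged not-estimable (never extrapolated) on rising or
non-positive tails; ratio tables refuse a non-positive reference mean;
the equivalent-concentration inversion refuses occupancies requiring
`kobs ≥ kinact` (unreachable at any concentration) and 100% exactly.

## Known limitations

* Naive-pooled and two-stage estimators are not NLME: pooled fits ignore
  inter-subject correlation, and two-stage CVs are biased upward by
  estimation noise.
* The occupancy model has a single central target pool; tissue or
  compartment-specific resynthesis is not represented.
* Default parameter sets are illustrative. Quantitative reproduction of
  any particular clinical occupancy trajectory requires fitting to that
  study's data; the package asserts structural behaviour only.
* The dose-proportionality verdict follows the CI-inclusion convention;
  no mixed-effects power model is provided.
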