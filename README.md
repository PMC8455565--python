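# btkpkpd

PK/PD modeling toolkit for covalent Bruton tyrosine kinase (BTK) inhibitor
programs: from preclinical exposure analysis through clinical target
occupancy to model-informed dose selection.

## Who this is for

Pharmacometricians and quantitative pharmacologists working on irreversible
(covalent) kinase inhibitors face a recurring puzzle: plasma concentrations
of the drug can be unquantifiable within hours of dosing while the target
stays fully occupied for days, because occupancy recovers only by protein
resynthesis. Empirical concentration-effect models mislead here; what is
needed is a turnover model of the target pool coupled to the drug's PK.
This package implements that chain end to end, together with the supporting
statistics (noncompartmental analysis, dose-proportionality assessment,
PD-efficacy correlation) and an in vitro / in vivo bridging layer for
projecting pathway inhibition across a clinical dose range. A synthetic-data
module generates study-shaped datasets (a rat collagen-induced-arthritis
PK/PD study and a human multiple-ascending-dose trial) so every stage is
testable without access to proprietary data.

## The models

**PK.** Two-compartment disposition with oral absorption through a chain of
n transit compartments:

    dA1/dt      = -ktr * A1                      (+ F * Dose at each event)
    dAi/dt      = ktr * (A(i-1) - Ai)            i = 2..n
    dAc/dt      = ktr * An - (CL/Vc + Q/Vc) Ac + (Q/Vp) Ap
    dAp/dt      = (Q/Vc) Ac - (Q/Vp) Ap
    C(t)        = Ac / Vc

**Target occupancy.** Free target F is produced at a zero-order rate ksyn,
degraded at first-order kdeg, and irreversibly inactivated by drug at a
second-order rate kbind * C(t); bound target clears at the same rate as
free target:

    dF/dt = ksyn - kdeg * F - kbind * C(t) * F
    dB/dt = kbind * C(t) * F - kdeg * B
    occupancy% = 100 * (1 - F / F0),   F0 = ksyn / kdeg

Because bound target clears at the free-target rate, F + B = F0 is an
exact invariant — used as a solver check. Under constant concentration the
steady state is the hyperbola `occ = 100 * kbind*C / (kdeg + kbind*C)`.

**Statistics.** NCA (Cmax/Tmax, linear-trapezoid AUClast, terminal λz,
AUCinf), dose-normalised exposure ratios, and the power model
`ln(exposure) = β0 + β1 ln(dose)` with a proportionality verdict from the
90% CI of β1 against the acceptance interval
`(1 + ln θL / ln r, 1 + ln θU / ln r)` for bioequivalence limits
(0.80, 1.25) and dose ratio r.

**Bridging.** Covalent assay potency `occ = 1 - exp(-kinact C t / (KI + C))`,
inverse-time IC50 rescaling, absolute IC50 from a 4-parameter-logistic fit
against control-defined signal windows, and sigmoid-Emax pathway-inhibition
tables (B-cell receptor, Fc receptor, Toll-like receptor pathways) over a
1–40 mg dose grid.

## Worked example

```python
import numpy as np
import btkpkpd as b

pk = b.PKParameters.default_human()          # illustrative, not fitted
turn = b.TurnoverParameters.default_human()  # target half-life ~3 days
reg = b.DosingRegimen(dose_amount=40.0, n_doses=14, interval=24.0)

grid = np.linspace(0.0, 14 * 24.0, 2000)
prof = b.simulate_occupancy(pk, turn, reg, grid)
summ = b.occupancy_summary(prof, threshold=80.0, window=(0.0, 48.0))
print(f"occupancy at 4 h:  {prof.occupancy_at(4.0):.1f}%")
print(f"occupancy at 48 h: {prof.occupancy_at(48.0):.1f}%")
print(f"hours above 80% in first 48 h: {summ['time_above_threshold']:.1f}")

ratios = b.dose_normalized_ratios(
    {0.3: {"AUClast": 2.0}, 1.0: {"AUClast": 10.0}, 3.0: {"AUClast": 49.9}}
)
print("AUC ratios:", ratios["AUClast"])
print(b.fit_power_model([0.3, 1.0, 3.0], [2.0, 10.0, 49.9]))
```

prints

```
occupancy at 4 h:  93.0%
occupancy at 48 h: 85.5%
hours above 80% in first 48 h: 46.6
AUC ratios: {0.3: 1.0, 1.0: 5.0, 3.0: 25.0}
beta1 = 1.396 (90% CI 1.166-1.626); acceptance 0.90-1.10; nonproportional (n=3)
```

The first block shows the covalent-inhibitor signature: a 40 mg daily dose
drives occupancy above 90% within hours and holds it above 80% essentially
throughout the first two days, even though plasma drug is mostly gone
between doses. The second block is the rat-study exposure arithmetic:
group-mean AUCs of 2.0 / 10.0 / 49.9 ng·h/mL across a 0.3 / 1 / 3 mg/kg
design normalise to 1.0 : 5.0 : 25.0 against a 10-fold dose range, and the
power-model slope of ~1.4 with its CI entirely above the 0.90–1.10
acceptance band flags the kinetics as supra-proportional.

A command-line interface mirrors the library
(`btkpkpd generate|simulate|nca|doseprop|fit|bridge`, each with
`--seed`/`--config`/`--out`); outputs are plain CSV/JSON with provenance
headers so identical configs reproduce identical bytes.

## Layout

- `src/btkpkpd/core.py` — domain types, units, long-format dataset I/O
- `src/btkpkpd/pk.py` — transit-absorption two-compartment simulation
- `src/btkpkpd/occupancy.py` — covalent turnover model and summaries
- `src/btkpkpd/nca.py` — noncompartmental analysis, ratio tables
- `src/btkpkpd/doseprop.py` — power model, acceptance range, correlations
- `src/btkpkpd/estimation.py` — naive-pooled / two-stage fitting
- `src/btkpkpd/bridging.py` — kinact/KI assay math, 4PL, Emax tables
- `src/btkpkpd/synthetic.py` — study-shaped synthetic data generators
- `src/btkpkpd/cli.py` — command-line pipeline

See `docs/methods.md` for modeling assumptions, parameter choices, and
limitations.
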