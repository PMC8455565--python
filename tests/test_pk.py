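import numpy as np
import pytest

from btkpkpd import (
    DosingRegimen,
    PKParameters,
    simulate_pk,
    steady_state_metrics,
    superposition_profile,
)
from btkpkpd.core import ValidationError
from btkpkpd.pk import ConcentrationProfile, simulate_pk_events

from conftest import aligned_grid


class TestSimulatePK:
    def test_no_dose_gives_zero_profile(self, two_cpt_params):
        prof = simulate_pk(two_cpt_params, None, np.linspace(0, 24, 50))
        assert np.allclose(prof.central_conc, 0.0)

    def test_matches_bateman_closed_form(self, one_cpt_params, single_dose):
        """Collapsed to one compartment with first-order absorption, the ODE
        route must match the Bateman double-exponential."""
        p = one_cpt_params
        grid = np.linspace(0, 48, 200)
        prof = simulate_pk(p, single_dose, grid)
        ka, ke = p.ktr, p.CL / p.Vc
        dose = single_dose.dose_amount
        expected = (
            p.F * dose * ka / (p.Vc * (ka - ke)) * (np.exp(-ke * grid) - np.exp(-ka * grid))
        ) * 1000.0  # mg/L -> ng/mL
        np.testing.assert_allclose(prof.central_conc[1:], expected[1:], rtol=1e-6)

    def test_mass_balance_with_full_bioavailability(self, two_cpt_params):
        reg = DosingRegimen(100.0, n_doses=3, interval=12.0)
        prof = simulate_pk(two_cpt_params, reg, np.linspace(0, 72, 100))
        total = prof.state.sum(axis=1)  # compartments + eliminated accumulator
        administered = np.where(
            prof.times[:, None] >= np.array([0.0, 12.0, 24.0])[None, :], 100.0, 0.0
        ).sum(axis=1)
        np.testing.assert_allclose(total[1:], administered[1:], rtol=1e-6)

    def test_dose_linearity(self, two_cpt_params):
        grid = np.linspace(0, 48, 80)
        c1 = simulate_pk(two_cpt_params, DosingRegimen(10.0), grid).central_conc
        c2 = simulate_pk(two_cpt_params, DosingRegimen(20.0), grid).central_conc
        np.testing.assert_allclose(c2[1:], 2.0 * c1[1:], rtol=1e-8)

    def test_states_nonnegative(self, two_cpt_params):
        reg = DosingRegimen(50.0, n_doses=5, interval=8.0)
        prof = simulate_pk(two_cpt_params, reg, np.linspace(0, 96, 300))
        assert prof.state.min() >= -1e-9

    def test_transit_chain_peak_approaches_mean_transit_time(self):
        """At fixed mean transit time n/ktr, the absorption-flux peak time
        moves toward the mean transit time as n grows."""
        mtt = 2.0
        grid = np.linspace(0, 24, 4801)
        peaks = []
        for n in (1, 3, 8, 20):
            p = PKParameters(CL=5, Vc=20, Q=0, Vp=0, ktr=n / mtt, F=1.0, n_transit=n)
            prof = simulate_pk(p, DosingRegimen(100.0), grid)
            flux = prof.state[:, n - 1] * p.ktr  # into the central compartment
            peaks.append(grid[np.argmax(flux)])
        errors = [abs(t - mtt) for t in peaks]
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < 0.3

    def test_grid_must_cover_dose_events(self, two_cpt_params):
        with pytest.raises(ValidationError):
            simulate_pk_events(two_cpt_params, [(0.0, 10.0)], np.linspace(5, 24, 10))


class TestSuperposition:
    def test_single_dose_is_identity(self, two_cpt_params, single_dose):
        grid = aligned_grid(48.0)
        prof = simulate_pk(two_cpt_params, single_dose, grid)
        sup = superposition_profile(two_cpt_params, single_dose, prof)
        np.testing.assert_allclose(sup.central_conc, prof.central_conc, rtol=1e-12)

    def test_two_doses_sum_shifted_copies(self, two_cpt_params):
        tau = 12.0
        grid = aligned_grid(72.0)
        single = simulate_pk(two_cpt_params, DosingRegimen(40.0), grid)
        sup = superposition_profile(
            two_cpt_params, DosingRegimen(40.0, n_doses=2, interval=tau), single
        )
        t_chk = grid[grid >= tau]
        manual = single.conc_at(t_chk) + single.conc_at(t_chk - tau)
        np.testing.assert_allclose(sup.conc_at(t_chk), manual, rtol=1e-10)

    def test_bid_28_doses_agrees_with_ode(self, two_cpt_params):
        """Linearity cross-check: 14 days of BID dosing by superposition of a
        single-dose simulation matches the full multi-dose ODE solution."""
        reg = DosingRegimen(40.0, n_doses=28, interval=12.0)
        grid = aligned_grid(28 * 12 + 48, step=0.25)
        single = simulate_pk(two_cpt_params, DosingRegimen(40.0), grid)
        sup = superposition_profile(two_cpt_params, reg, single)
        ode = simulate_pk(two_cpt_params, reg, grid)
        mask = ode.central_conc > 1e-3  # relative comparison where defined
        np.testing.assert_allclose(
            sup.central_conc[mask], ode.central_conc[mask], rtol=1e-4
        )


class TestSteadyStateMetrics:
    def _constant_profile(self, c, t_end=48.0):
        t = np.linspace(0, t_end, 100)
        return ConcentrationProfile(
            times=t, central_conc=np.full_like(t, c), state=np.zeros((t.size, 0)), state_labels=[]
        )

    def test_constant_profile(self):
        m = steady_state_metrics(self._constant_profile(7.5), interval=24.0, last_dose_time=12.0)
        assert m["Cmax_ss"] == m["Cmin_ss"] == pytest.approx(7.5)
        assert m["AUC_tau"] == pytest.approx(7.5 * 24.0)

    def test_single_dose_window_equals_single_dose_metrics(self, two_cpt_params, single_dose):
        grid = np.linspace(0, 24, 1000)
        prof = simulate_pk(two_cpt_params, single_dose, grid)
        m = steady_state_metrics(prof, interval=24.0, last_dose_time=0.0)
        assert m["Cmax_ss"] == pytest.approx(prof.central_conc.max())
        assert m["AUC_tau"] == pytest.approx(np.trapezoid(prof.central_conc, grid), rel=1e-9)

    def test_auc_tau_at_steady_state_equals_single_dose_aucinf(self, two_cpt_params):
        """For linear PK, AUC over one interval at steady state equals the
        single-dose AUC extrapolated to infinity."""
        reg = DosingRegimen(40.0, n_doses=40, interval=12.0)
        grid = aligned_grid(reg.last_dose_time + 12.0, step=0.05)
        prof = simulate_pk(two_cpt_params, reg, grid)
        m = steady_state_metrics(prof, interval=12.0, last_dose_time=reg.last_dose_time)
        long_grid = aligned_grid(2000.0, step=0.05)
        single = simulate_pk(two_cpt_params, DosingRegimen(40.0), long_grid)
        auc_inf = np.trapezoid(single.central_conc, long_grid)
        assert m["AUC_tau"] == pytest.approx(auc_inf, rel=0.01)

    def test_accumulation_raises_trough(self, two_cpt_params):
        reg = DosingRegimen(40.0, n_doses=10, interval=12.0)
        grid = aligned_grid(10 * 12 + 12, step=0.25)
        prof = simulate_pk(two_cpt_params, reg, grid)
        first = steady_state_metrics(prof, interval=12.0, last_dose_time=0.0)
        last = steady_state_metrics(prof, interval=12.0, last_dose_time=reg.last_dose_time)
        assert last["Cmin_ss"] >= first["Cmin_ss"]

    def test_insufficient_coverage_errors(self, two_cpt_params, single_dose):
        prof = simulate_pk(two_cpt_params, single_dose, np.linspace(0, 10, 50))
        with pytest.raises(ValidationError):
            steady_state_metrics(prof, interval=24.0, last_dose_time=0.0)
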