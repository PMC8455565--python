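import math

import numpy as np
import pytest

from btkpkpd import (
    CovalentAssayModel,
    EmaxModel,
    PKParameters,
    TurnoverParameters,
    covalent_ic50_time_scaling,
    equivalent_invitro_concentration,
    fit_4pl_absolute_ic50,
    invitro_occupancy,
    pathway_inhibition_table,
)
from btkpkpd.core import ValidationError


@pytest.fixture
def assay():
    return CovalentAssayModel(kinact=5.0, KI=50.0, incubation_time=1.0)


class TestInvitroOccupancy:
    def test_zero_concentration(self, assay):
        assert invitro_occupancy(0.0, assay) == 0.0

    def test_half_life_identity_at_saturation(self):
        """With C >> KI, kobs = kinact; an incubation of ln2/kinact leaves
        exactly half the target unmodified."""
        model = CovalentAssayModel(kinact=2.0, KI=1.0, incubation_time=math.log(2) / 2.0)
        assert invitro_occupancy(1e7, model) == pytest.approx(0.5, rel=1e-5)

    def test_linear_regime_ic50(self):
        """For C << KI, occupancy = 1 - exp(-(kinact/KI) C t), so the IC50
        satisfies C t = ln2 KI / kinact.  The IC50/KI ratio equals
        ln2/(kinact t); a large kinact t puts the IC50 deep in the linear
        regime where the identity is near-exact."""
        scaled = CovalentAssayModel(kinact=700.0, KI=50.0, incubation_time=1.0)
        c50 = math.log(2) * scaled.KI / (scaled.kinact * scaled.incubation_time)
        assert c50 / scaled.KI < 1e-3
        assert invitro_occupancy(c50, scaled) == pytest.approx(0.5, rel=1e-3)
        assert scaled.ic50_linear == pytest.approx(c50)

    def test_monotone_in_concentration(self, assay):
        c = np.logspace(-2, 4, 50)
        occ = invitro_occupancy(c, assay)
        assert np.all(np.diff(occ) > 0)
        assert np.all((occ >= 0) & (occ <= 1))


class TestIC50TimeScaling:
    def test_identity(self):
        assert covalent_ic50_time_scaling(12.0, 1.0, 1.0) == 12.0

    def test_doubling_time_halves_ic50(self):
        assert covalent_ic50_time_scaling(12.0, 1.0, 2.0) == pytest.approx(6.0)

    def test_inverse_kt_product(self):
        # ic50 = ln2/(k t): k = 0.001 (nM h)^-1 at t = 1 h gives 693.1 nM
        k = 0.001
        ic50 = math.log(2) / (k * 1.0)
        assert ic50 == pytest.approx(693.1, abs=0.1)
        assert covalent_ic50_time_scaling(ic50, 1.0, 2.0) == pytest.approx(math.log(2) / (k * 2.0))

    def test_composition(self):
        step = covalent_ic50_time_scaling(covalent_ic50_time_scaling(9.0, 1.0, 4.0), 4.0, 24.0)
        direct = covalent_ic50_time_scaling(9.0, 1.0, 24.0)
        assert step == pytest.approx(direct, rel=1e-12)


class TestFourPL:
    CONCS = 1000.0 / 3.0 ** np.arange(8)

    @staticmethod
    def _response(concs, top=100.0, bottom=2.0, ic50=15.0, hill=1.2):
        return bottom + (top - bottom) / (1.0 + (concs / ic50) ** hill)

    def test_exact_recovery(self):
        resp = self._response(self.CONCS)
        fit = fit_4pl_absolute_ic50(self.CONCS, resp, max_control=100.0, min_control=2.0)
        assert fit.determinable
        assert fit.ic50_abs == pytest.approx(15.0, rel=1e-4)

    def test_flat_response_not_determinable(self):
        resp = np.full(8, 100.0)
        fit = fit_4pl_absolute_ic50(self.CONCS, resp, max_control=100.0, min_control=2.0)
        assert not fit.determinable and fit.ic50_abs is None

    def test_signal_axis_affine_invariance(self):
        """Rescaling the raw signal (and its controls) by the same affine
        map leaves the absolute IC50 unchanged."""
        resp = self._response(self.CONCS)
        f1 = fit_4pl_absolute_ic50(self.CONCS, resp, 100.0, 2.0)
        f2 = fit_4pl_absolute_ic50(self.CONCS, 3.0 * resp + 7.0, 3.0 * 100.0 + 7.0, 3.0 * 2.0 + 7.0)
        assert f2.ic50_abs == pytest.approx(f1.ic50_abs, rel=1e-6)

    def test_absolute_vs_relative_ic50_with_partial_inhibition(self):
        """When the curve bottoms out above the min control, the absolute
        IC50 (control-window midpoint) is right-shifted from the relative
        IC50 (curve inflection)."""
        resp = self._response(self.CONCS, bottom=40.0)
        fit = fit_4pl_absolute_ic50(self.CONCS, resp, max_control=100.0, min_control=2.0)
        assert fit.determinable
        assert fit.ic50_abs > 15.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_4pl_absolute_ic50([1, 10, 100], [90, 50, 10], 100.0, 0.0)


class TestEquivalentConcentration:
    def test_zero_occupancy(self, assay):
        assert equivalent_invitro_concentration(0.0, assay) == 0.0

    def test_linear_regime_half_occupancy(self):
        # kinact t / KI = 100 ln2 per nM puts 50% occupancy near 1 nM
        model = CovalentAssayModel(kinact=100 * math.log(2), KI=100.0, incubation_time=1.0)
        c = equivalent_invitro_concentration(50.0, model)
        assert c == pytest.approx(1.0, rel=0.02)  # linear-regime closed form
        assert invitro_occupancy(c, model) == pytest.approx(0.5, rel=1e-10)

    def test_round_trip_over_grid(self, assay):
        for occ in np.linspace(1.0, 99.0, 25):
            c = equivalent_invitro_concentration(occ, assay)
            assert invitro_occupancy(c, assay) * 100.0 == pytest.approx(occ, abs=1e-8)

    def test_full_occupancy_rejected(self, assay):
        with pytest.raises(ValidationError):
            equivalent_invitro_concentration(100.0, assay)

    def test_unreachable_occupancy_rejected(self):
        slow = CovalentAssayModel(kinact=0.1, KI=10.0, incubation_time=1.0)
        # 99% occupancy needs kobs = 4.6/h > kinact
        with pytest.raises(ValidationError, match="unreachable"):
            equivalent_invitro_concentration(99.0, slow)


class TestPathwayInhibitionTable:
    @pytest.fixture
    def setup(self, assay):
        pk = PKParameters.default_human()
        turnover = TurnoverParameters.default_human()
        pathways = {
            "bcr_activation": EmaxModel(emax=1.0, ec50=5.0),
            "fcr_activation": EmaxModel(emax=0.9, ec50=20.0),
            "tlr_activation": EmaxModel(emax=0.8, ec50=40.0),
        }
        return pk, turnover, pathways, assay

    def test_zero_dose_gives_zero_inhibition(self, setup):
        pk, turnover, pathways, assay = setup
        table = pathway_inhibition_table([0.0], pk, turnover, pathways, assay)
        assert float(table.loc[0.0, "bcr_activation"]) == 0.0

    def test_half_max_at_matched_ec50(self, setup):
        pk, turnover, _, assay = setup
        table = pathway_inhibition_table([10.0], pk, turnover, {"probe": EmaxModel(emax=1.0, ec50=1.0)}, assay)
        c_eq = float(table["c_eq_nM"].iloc[0])
        matched = {"probe": EmaxModel(emax=0.8, ec50=c_eq)}
        table2 = pathway_inhibition_table([10.0], pk, turnover, matched, assay)
        assert float(table2["probe"].iloc[0]) == pytest.approx(0.4, rel=1e-6)

    def test_monotone_in_dose_and_bounded(self, setup):
        pk, turnover, pathways, assay = setup
        doses = [1.0, 3.0, 5.0, 10.0, 20.0, 30.0, 40.0]
        table = pathway_inhibition_table(doses, pk, turnover, pathways, assay)
        for name in pathways:
            col = table[name].to_numpy()
            assert np.all(np.diff(col) >= -1e-9)
            assert np.all((col >= 0) & (col <= 1))

    def test_trough_statistic_below_average(self, setup):
        pk, turnover, pathways, assay = setup
        avg = pathway_inhibition_table([20.0], pk, turnover, pathways, assay)
        tro = pathway_inhibition_table(
            [20.0], pk, turnover, pathways, assay, occupancy_statistic="trough"
        )
        assert float(tro["occupancy_ss_pct"].iloc[0]) <= float(avg["occupancy_ss_pct"].iloc[0])

    def test_empty_pathways_rejected(self, setup):
        pk, turnover, _, assay = setup
        with pytest.raises(ValidationError):
            pathway_inhibition_table([10.0], pk, turnover, {}, assay)
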