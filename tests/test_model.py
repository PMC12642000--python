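"""Core ODE model: right-hand side, simulator, AUC."""

import numpy as np
import pytest

import igpbpk as ig
from igpbpk.model import baseline_state

from conftest import REF_70KG, expm_plasma_profile


def _drug(**kw):
    base = dict(clearance=0.045, sigma_tight=0.97, sigma_leaky=0.94)
    base.update(kw)
    return ig.DrugParams(**base)


class TestOdeRhs:
    def test_zero_state_no_dose_is_fixed_point(self, physio_70kg, ivig_drug):
        dx = ig.ode_rhs(np.zeros(5), 0.0, physio_70kg, ivig_drug, [])
        assert np.all(dx == 0.0)

    def test_mass_conserved_without_clearance(self, physio_70kg):
        # negligible clearance, full IM bioavailability: total amount is conserved
        drug = _drug(clearance=1e-12, ka=0.7, bioavailability_im=1.0)
        state = np.array([3.0, 1.5, 0.7, 0.2, 4.0])
        dx = ig.ode_rhs(state, 1.0, physio_70kg, drug, [])
        assert abs(dx.sum()) < 1e-10

    def test_depot_first_order_transfer(self, physio_70kg):
        drug = _drug(ka=1.0, bioavailability_im=0.8)
        state = np.array([0.0, 0.0, 0.0, 0.0, 5.0])
        dx = ig.ode_rhs(state, 0.0, physio_70kg, drug, [])
        assert dx[4] == pytest.approx(-5.0)
        assert dx[0] == pytest.approx(0.8 * 5.0)

    def test_nonfinite_state_names_compartment(self, physio_70kg, ivig_drug):
        state = np.array([0.0, np.nan, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="tight"):
            ig.ode_rhs(state, 0.0, physio_70kg, ivig_drug, [])

    def test_infusion_feeds_plasma_only(self, physio_70kg, ivig_drug, ivig_dose):
        dx = ig.ode_rhs(np.zeros(5), 0.05, physio_70kg, ivig_drug, [ivig_dose])
        assert dx[0] == pytest.approx(ivig_dose.amount / ivig_dose.infusion_duration)
        assert np.all(dx[1:] == 0.0)


class TestSimulate:
    def test_baseline_steady_state_holds_100_days(self, physio_70kg, ivig_drug):
        times = np.linspace(0.0, 100.0, 60)[1:]
        prof = ig.simulate(physio_70kg, ivig_drug, [], times, superpose_baseline=True)
        expected = baseline_state(physio_70kg, ivig_drug)
        for series, value in zip(
            (prof.plasma, prof.tight, prof.leaky, prof.lymph), expected
        ):
            assert np.max(np.abs(series - value)) / value < 1e-6

    def test_instant_mixing_limit(self, reference):
        # negligible clearance and lymph flow: plasma ~ baseline + D/Vp
        physio = ig.scale_physiology(reference, 70.0, 0).model_copy(
            update={"lymph_flow_total": 1e-8}
        )
        drug = _drug(clearance=1e-10, baseline_conc=13.0)
        dose = ig.DoseEvent(
            route=ig.Route.IV_INFUSION, amount=31.5, infusion_duration=0.01
        )
        prof = ig.simulate(physio, drug, [dose], np.array([0.011]), superpose_baseline=True)
        assert prof.plasma[0] == pytest.approx(13.0 + 31.5 / 2.6, rel=1e-6)

    def test_matches_matrix_exponential_oracle(self, physio_70kg, ivig_drug, ivig_dose):
        """Numerical integration agrees with the linear-system closed form."""
        times = np.unique(np.concatenate([np.linspace(0.0, 28.0, 120), [1.0 / 6.0]]))
        prof = ig.simulate(physio_70kg, ivig_drug, [ivig_dose], times)
        oracle = expm_plasma_profile(
            times, dose_amount=ivig_dose.amount,
            infusion_duration=ivig_dose.infusion_duration, **REF_70KG,
        )
        mask = times > 0
        rel = np.abs(prof.plasma[mask] - oracle[mask]) / oracle[mask]
        assert rel.max() < 1e-6

    def test_im_route_matches_oracle(self, physio_70kg):
        drug = _drug(ka=0.25, bioavailability_im=0.8)
        dose = ig.DoseEvent(route=ig.Route.IM, amount=3e-4)
        times = np.linspace(0.0, 56.0, 80)[1:]
        prof = ig.simulate(physio_70kg, drug, [dose], times)
        oracle = expm_plasma_profile(
            times, dose_amount=3e-4, infusion_duration=0.0,
            ka=0.25, bioavailability_im=0.8, im=True, **REF_70KG,
        )
        rel = np.abs(prof.plasma - oracle) / oracle
        assert rel.max() < 1e-6

    def test_dose_linearity(self, physio_70kg, ivig_drug):
        times = np.linspace(0.0, 28.0, 50)[1:]
        profs = []
        for amount in (10.0, 30.0):
            dose = ig.DoseEvent(
                route=ig.Route.IV_INFUSION, amount=amount, infusion_duration=1.0 / 6.0
            )
            profs.append(ig.simulate(physio_70kg, ivig_drug, [dose], times).plasma)
        assert np.allclose(3.0 * profs[0], profs[1], rtol=1e-8)

    def test_mass_balance_after_dosing(self, physio_70kg):
        drug = _drug(clearance=1e-12)
        dose = ig.DoseEvent(
            route=ig.Route.IV_INFUSION, amount=31.5, infusion_duration=1.0 / 6.0
        )
        times = np.linspace(0.5, 60.0, 40)
        prof = ig.simulate(physio_70kg, drug, [dose], times)
        totals = prof.amounts.sum(axis=1)
        assert np.max(np.abs(totals - 31.5)) / 31.5 < 1e-8

    def test_fast_im_absorption_approaches_iv_bolus(self, physio_70kg):
        drug = _drug(ka=1e4, bioavailability_im=1.0)
        times = np.linspace(0.01, 28.0, 60)
        im = ig.simulate(physio_70kg, drug, [ig.DoseEvent(route=ig.Route.IM, amount=31.5)], times)
        bolus = ig.DoseEvent(
            route=ig.Route.IV_INFUSION, amount=31.5, infusion_duration=1e-6
        )
        iv = ig.simulate(physio_70kg, drug, [bolus], times)
        rel = np.abs(im.plasma - iv.plasma) / iv.plasma
        assert rel.max() < 0.01

    @pytest.mark.parametrize(
        "bad_times, message",
        [(np.array([-1.0, 2.0]), "before t=0"), (np.array([2.0, 1.0]), "increasing")],
    )
    def test_grid_validation(self, physio_70kg, ivig_drug, bad_times, message):
        with pytest.raises(ValueError, match=message):
            ig.simulate(physio_70kg, ivig_drug, [], bad_times)

    def test_im_without_ka_is_rejected(self, physio_70kg):
        drug = _drug(ka=None)
        with pytest.raises(ValueError, match="ka"):
            ig.simulate(
                physio_70kg, drug, [ig.DoseEvent(route=ig.Route.IM, amount=1.0)],
                np.array([1.0]),
            )


class TestAucInf:
    def test_iv_closed_form(self, physio_70kg):
        """AUC-inf of a 37-g IV dose at CL = 0.045 L/day is 822.2 g*day/L."""
        drug = _drug()
        dose = ig.DoseEvent(route=ig.Route.IV_INFUSION, amount=37.0, infusion_duration=1.0 / 6.0)
        auc = ig.exogenous_auc_inf(physio_70kg, drug, dose)
        assert auc == pytest.approx(37.0 / 0.045, rel=1e-3)

    def test_im_scales_with_bioavailability(self, physio_70kg):
        drug = _drug(ka=0.25, bioavailability_im=0.8, clearance=0.03)
        dose = ig.DoseEvent(route=ig.Route.IM, amount=3e-4)
        auc = ig.exogenous_auc_inf(physio_70kg, drug, dose)
        assert auc == pytest.approx(0.8 * 3e-4 / 0.03, rel=1e-3)

    def test_linearity_in_dose(self, physio_70kg):
        drug = _drug()
        aucs = [
            ig.exogenous_auc_inf(
                physio_70kg, drug,
                ig.DoseEvent(route=ig.Route.IV_INFUSION, amount=a, infusion_duration=0.1),
            )
            for a in (10.0, 20.0)
        ]
        assert aucs[1] == pytest.approx(2.0 * aucs[0], rel=1e-6)


class TestDomainTypes:
    def test_physiology_invariants(self):
        with pytest.raises(ValueError):
            ig.PhysiologyParams(
                plasma_volume=-1, tight_volume=8, leaky_volume=4, lymph_volume=5,
                lymph_flow_total=2.9,
            )
        with pytest.raises(ValueError):
            ig.PhysiologyParams(
                plasma_volume=2.6, tight_volume=8, leaky_volume=4, lymph_volume=5,
                lymph_flow_total=2.9, sigma_lymph=1.0,
            )

    def test_drug_invariants(self):
        with pytest.raises(ValueError, match="sigma_tight"):
            ig.DrugParams(clearance=0.045, sigma_tight=0.5, sigma_leaky=0.9)
        with pytest.raises(ValueError):
            ig.DrugParams(clearance=0.0)

    def test_dose_event_invariants(self):
        with pytest.raises(ValueError, match="infusion_duration"):
            ig.DoseEvent(route=ig.Route.IV_INFUSION, amount=1.0)
        ev = ig.DoseEvent(route=ig.Route.IM, amount=1.0, start_time=2.0)
        assert ev.end_time == 2.0

    def test_profile_requires_increasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            ig.ConcentrationProfile(
                times=np.array([1.0, 1.0]), plasma=np.zeros(2), tight=np.zeros(2),
                leaky=np.zeros(2), lymph=np.zeros(2), depot_amount=np.zeros(2),
            )
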