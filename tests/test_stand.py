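import numpy as np
import pytest

from forestmit import ConfigurationError, InputError
from forestmit.forcing import generate_climate
from forestmit.harvest import HarvestParams
from forestmit.stand import (
    Cohort,
    PatchState,
    StandParams,
    annual_growth,
    decay_dead_pools,
    disturbance_step,
    initialize_stand,
    scheduled_harvest,
    simulate,
)

from conftest import make_scenario


def flat_climate(dT=0.0):
    return generate_climate("RCP4.5", noise_sd=0.0, end_anomaly=dT)


class TestInitializeStand:
    def test_mature_founding_cohorts(self, base_scenario):
        state = initialize_stand(base_scenario, StandParams(n_patches=3))
        for patch in state.patches:
            years = sorted(c.establishment_year for c in patch.cohorts)
            assert years == list(range(1921, 1941))

    def test_young_founding_cohorts(self, base_scenario):
        sc = make_scenario(base_scenario, forest_age="young", forest_type="BD")
        state = initialize_stand(sc, StandParams(n_patches=2))
        years = sorted(c.establishment_year for c in state.patches[0].cohorts)
        assert years == list(range(1981, 2001))

    def test_single_patch(self, base_scenario):
        state = initialize_stand(base_scenario, StandParams(n_patches=1))
        assert len(state.patches) == 1

    def test_phases_staggered_within_interval(self, base_scenario):
        params = StandParams(n_patches=50)
        state = initialize_stand(base_scenario, params, seed=3)
        phases = {p.harvest_phase for p in state.patches}
        assert all(0 <= ph < 20 for ph in phases)
        assert len(phases) > 5  # actually staggered

    def test_unknown_age_label(self, base_scenario):
        sc = make_scenario(base_scenario, forest_age="ancient")
        with pytest.raises(ConfigurationError):
            initialize_stand(sc, StandParams(n_patches=1))


class TestAnnualGrowth:
    def test_saturated_stand_has_zero_npp(self):
        params = StandParams(n_patches=1)
        patch = PatchState(cohorts=[Cohort(1900, params.carrying_capacity)])
        npp, _ = annual_growth(patch, 0.0, params, 2000)
        assert npp == 0.0

    def test_empty_stand_full_npp_to_new_cohort(self):
        params = StandParams(n_patches=1, background_mortality=0.0)
        patch = PatchState(cohorts=[Cohort(2000, 0.0)])
        npp, _ = annual_growth(patch, 0.0, params, 2000)
        assert npp == pytest.approx(params.npp_max)
        assert patch.cohorts[0].biomass == pytest.approx(params.npp_max)

    def test_equal_split_among_zero_biomass_cohorts(self):
        params = StandParams(n_patches=1, background_mortality=0.0)
        patch = PatchState(cohorts=[Cohort(2000, 0.0), Cohort(2000, 0.0)])
        npp, _ = annual_growth(patch, 0.0, params, 2000)
        assert patch.cohorts[0].biomass == pytest.approx(npp / 2)
        assert patch.cohorts[1].biomass == pytest.approx(npp / 2)

    def test_climate_modifier_cancels_at_dT5(self):
        # 1 + 0.05*5 - 0.01*25 = 1 with default coefficients
        params = StandParams(n_patches=1, background_mortality=0.0)
        p0 = PatchState(cohorts=[Cohort(1990, 1.0)])
        p5 = PatchState(cohorts=[Cohort(1990, 1.0)])
        npp0, _ = annual_growth(p0, 0.0, params, 2000)
        npp5, _ = annual_growth(p5, 5.0, params, 2000)
        assert npp5 == pytest.approx(npp0)

    def test_mortality_routed_to_deadwood(self):
        params = StandParams(n_patches=1)
        patch = PatchState(cohorts=[Cohort(1900, 10.0)])
        _, mort = annual_growth(patch, 0.0, params, 2000)
        assert mort > 0
        assert patch.deadwood == pytest.approx(mort)

    def test_unplanted_cohorts_do_not_grow(self):
        params = StandParams(n_patches=1)
        patch = PatchState(cohorts=[Cohort(2050, 0.0)])
        npp, mort = annual_growth(patch, 0.0, params, 2000)
        assert npp == 0.0 and mort == 0.0


class TestDisturbanceStep:
    def test_no_event_when_p_zero(self):
        patch = PatchState(cohorts=[Cohort(1950, 5.0)])
        assert disturbance_step(patch, 0.5, 0.0, 2000) is None
        assert patch.vegetation() == 5.0

    def test_event_kills_all_established(self):
        patch = PatchState(cohorts=[Cohort(1950, 5.0), Cohort(1980, 2.0)])
        kill = disturbance_step(patch, 0.0, 1 / 300, 2000)
        assert kill is not None
        assert kill.total == pytest.approx(7.0)
        assert kill.killed_by_age == {50: 5.0, 20: 2.0}
        assert patch.vegetation() == 0.0

    def test_future_cohorts_survive(self):
        patch = PatchState(cohorts=[Cohort(1950, 5.0), Cohort(2010, 0.0)])
        disturbance_step(patch, 0.0, 0.5, 2000)
        assert [c.establishment_year for c in patch.cohorts] == [2010]

    def test_invalid_probability(self):
        patch = PatchState()
        with pytest.raises(ConfigurationError):
            disturbance_step(patch, 0.5, 1.5, 2000)


class TestScheduledHarvest:
    def _patch(self, est=1990, biomass=1.0, phase=None, year=2030, interval=20):
        if phase is None:
            phase = year % interval
        return PatchState(cohorts=[Cohort(est, biomass)], harvest_phase=phase)

    def test_zero_intensity_after_2020(self, base_scenario):
        sc = make_scenario(base_scenario, harvest_intensity=0.0)
        params = StandParams()
        patch = self._patch()
        assert scheduled_harvest(patch, 2030, sc, params, HarvestParams()) is None
        assert patch.cohorts[0].biomass == 1.0

    def test_intensity_150_removal_fraction(self, base_scenario):
        sc = make_scenario(base_scenario, harvest_intensity=1.5)
        patch = self._patch()
        ev = scheduled_harvest(patch, 2030, sc, StandParams(), HarvestParams())
        assert ev is not None
        # 0.24 * 1.5 = 0.36 of the cohort
        assert patch.cohorts[0].biomass == pytest.approx(1.0 - 0.36)
        assert ev.total == pytest.approx(0.36, rel=1e-12)

    def test_baseline_intensity_before_2021(self, base_scenario):
        sc = make_scenario(base_scenario, harvest_intensity=0.0)
        patch = self._patch(est=1950, year=2000)
        ev = scheduled_harvest(patch, 2000, sc, StandParams(), HarvestParams())
        assert ev is not None  # pre-2021 always cuts at the baseline fraction
        assert ev.total == pytest.approx(0.24, rel=1e-12)

    def test_young_cohort_carbon_is_firewood(self, base_scenario):
        patch = self._patch(est=2015, year=2030)  # 15 years old at event
        ev = scheduled_harvest(patch, 2030, base_scenario, StandParams(),
                               HarvestParams())
        assert ev.firewood == pytest.approx(ev.total)
        assert ev.removed_stem == 0.0

    def test_off_phase_year_does_nothing(self, base_scenario):
        patch = self._patch(phase=3, year=2030)
        assert scheduled_harvest(patch, 2030, base_scenario, StandParams(),
                                 HarvestParams()) is None

    def test_residue_booked_to_deadwood(self, base_scenario):
        patch = self._patch()
        ev = scheduled_harvest(patch, 2030, base_scenario, StandParams(),
                               HarvestParams())
        assert patch.deadwood == pytest.approx(ev.residue)


class TestDecayDeadPools:
    def test_default_rates(self):
        params = StandParams(n_patches=1)
        patch = PatchState(deadwood=1.0, soil=0.0)
        dw_resp, to_soil, soil_resp = decay_dead_pools(patch, 0.0, params)
        assert dw_resp + to_soil == pytest.approx(0.04)
        assert to_soil == pytest.approx(0.012)
        assert dw_resp == pytest.approx(0.028)
        assert patch.deadwood == pytest.approx(0.96)

    def test_q10_doubles_at_10_degrees(self):
        params = StandParams(n_patches=1)
        patch = PatchState(deadwood=1.0)
        dw_resp, to_soil, _ = decay_dead_pools(patch, 10.0, params)
        assert dw_resp + to_soil == pytest.approx(0.08)

    def test_empty_pools_no_flux(self):
        patch = PatchState()
        assert decay_dead_pools(patch, 0.0, StandParams()) == (0.0, 0.0, 0.0)

    def test_soil_respiration(self):
        params = StandParams(n_patches=1)
        patch = PatchState(soil=2.0)
        _, _, soil_resp = decay_dead_pools(patch, 0.0, params)
        assert soil_resp == pytest.approx(2.0 * 0.01)


class TestSimulate:
    def test_deterministic(self, base_scenario):
        clim = generate_climate("RCP4.5", seed=2)
        params = StandParams(n_patches=4)
        a = simulate(base_scenario, clim, params, seed=2)
        b = simulate(base_scenario, clim, params, seed=2)
        np.testing.assert_array_equal(a.veg, b.veg)
        for name in a.fluxes:
            np.testing.assert_array_equal(a.fluxes[name], b.fluxes[name])

    def test_annual_closure(self, base_scenario):
        sc = make_scenario(base_scenario, rcp="RCP8.5", salvage=True)
        clim = generate_climate("RCP8.5", seed=4)
        out = simulate(sc, clim, StandParams(n_patches=5), seed=4)
        scale = np.max(out.veg + out.deadwood + out.soil)
        assert np.abs(out.closure_residual()).max() <= 1e-9 * scale

    def test_no_negative_pools_or_fluxes(self, base_scenario):
        sc = make_scenario(base_scenario, rcp="RCP8.5", harvest_intensity=1.5,
                           salvage=True)
        clim = generate_climate("RCP8.5", seed=9)
        out = simulate(sc, clim, StandParams(n_patches=5), seed=9)
        assert (out.veg >= 0).all()
        assert (out.deadwood >= 0).all()
        assert (out.soil >= 0).all()
        for series in out.fluxes.values():
            assert (series >= 0).all()

    def test_monotone_approach_to_equilibrium_matches_logistic_map(
        self, base_scenario
    ):
        # oracle: the aggregate biomass follows the discrete logistic map
        # B <- B + npp_max*(1 - B/K) exactly when mortality, harvest and
        # disturbance are switched off
        params = StandParams(
            n_patches=1, background_mortality=0.0, harvest_fraction=0.0,
            disturbance_interval_ne=10**9, disturbance_interval_bd=10**9,
        )
        out = simulate(base_scenario, flat_climate(), params)
        expected = np.zeros(len(out.years))
        B = 0.0
        for t, year in enumerate(out.years):
            if year >= 1921:
                B = B + params.npp_max * (1 - B / params.carrying_capacity)
            expected[t] = B
        np.testing.assert_allclose(out.veg, expected, rtol=1e-12, atol=1e-12)
        assert (np.diff(out.veg) >= -1e-12).all()

    def test_equilibrium_reaches_K_at_reference_calibration(self, base_scenario):
        # at the reference density feedback (K=18) an undisturbed, unharvested
        # mature stand closes to within 1% of carrying capacity by 2100
        params = StandParams(
            n_patches=1, carrying_capacity=18.0, background_mortality=0.0,
            harvest_fraction=0.0,
            disturbance_interval_ne=10**9, disturbance_interval_bd=10**9,
        )
        out = simulate(base_scenario, flat_climate(), params)
        assert out.veg[-1] >= 0.99 * 18.0

    def test_disturbance_count_matches_binomial(self, base_scenario):
        # constant p = 1/300, 100 patches, 80 years -> Binomial(8000, 1/300)
        sc = make_scenario(base_scenario, disturbance_response="constant")
        clim = generate_climate("RCP4.5", seed=11)
        params = StandParams(n_patches=100)
        out = simulate(sc, clim, params, seed=11,
                       start_year=1920, end_year=1999)
        n, p = 100 * 80, 1 / 300
        sd = np.sqrt(n * p * (1 - p))
        assert abs(out.event_count.sum() - n * p) <= 3 * sd

    def test_coupling_event_superset(self, base_scenario):
        # shared uniform draws: cumulative event counts ordered by response
        clim = generate_climate("RCP8.5", seed=6, noise_sd=0.0)
        params = StandParams(n_patches=20)
        counts = {}
        for resp in ("constant", "linear", "exponential"):
            sc = make_scenario(base_scenario, rcp="RCP8.5",
                               disturbance_response=resp)
            out = simulate(sc, clim, params, seed=6)
            counts[resp] = np.cumsum(out.event_count)
        assert (counts["constant"] <= counts["linear"]).all()
        assert (counts["constant"] <= counts["exponential"]).all()
        # the linear curve exceeds the exponential one below +1 degC, so the
        # strict linear <= exponential ordering only binds late-century
        assert counts["exponential"][-1] >= counts["linear"][-1]
        assert counts["exponential"][-1] > counts["constant"][-1]

    def test_salvage_changes_post2020_only(self, base_scenario):
        clim = generate_climate("RCP8.5", seed=8)
        params = StandParams(n_patches=10)
        off = simulate(base_scenario, clim, params, seed=8)
        on = simulate(make_scenario(base_scenario, salvage=True), clim, params,
                      seed=8)
        pre = off.years <= 2020
        np.testing.assert_array_equal(off.veg[pre], on.veg[pre])
        np.testing.assert_array_equal(
            off.fluxes["removed_stem"][pre], on.fluxes["removed_stem"][pre]
        )

    def test_climate_must_cover_span(self, base_scenario):
        clim = generate_climate("RCP4.5", start_year=1950)
        with pytest.raises(InputError):
            simulate(base_scenario, clim, StandParams(n_patches=1))

    def test_accounts_view(self, base_scenario):
        clim = generate_climate("RCP4.5", seed=1)
        out = simulate(base_scenario, clim, StandParams(n_patches=2), seed=1)
        acc = out.accounts(2000)
        assert acc.npp == out.fluxes["npp"][2000 - 1920]
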