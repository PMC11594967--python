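"""Life-cycle integration: events, stage rules, survival and oracles."""

import math

import numpy as np
import pytest

from chirodeb import (
    ForcingScenario,
    OrganismState,
    Stage,
    compute_fluxes,
    egg_number,
    initial_reserve,
    pupation_transition,
    simulate_lifecycle,
    temperature_correction,
)
from chirodeb.sweep import sweep_food, sweep_temperature


class TestInitialReserve:
    def test_birth_event_and_maternal_condition(self, params):
        E0, age, birth = initial_reserve(params)
        # the birth event is located at EH = EHb and the solved egg energy
        # puts the hatchling exactly at the abundant-food reserve density
        assert birth.EH == pytest.approx(params.EHb, rel=1e-6)
        assert birth.E / (params.Em * birth.V) == pytest.approx(1.0, rel=1e-6)
        assert birth.E < E0  # the embryo spends reserve and cannot assimilate

    def test_temperature_scales_age_not_state(self, params):
        E0_ref, age_ref, b_ref = initial_reserve(params)
        E0_15, age_15, b_15 = initial_reserve(params, 288.15)
        assert E0_15 == E0_ref
        assert b_15.V == b_ref.V and b_15.E == b_ref.E
        cT = temperature_correction(288.15, params)
        assert age_15 == pytest.approx(age_ref / cT, rel=1e-12)


class TestAdLibitumLifeCycle:
    def test_event_ages_strictly_ordered(self, report21):
        ages = [0.0, report21.age_at_molt1, report21.age_at_molt2,
                report21.age_at_puberty, report21.age_at_phase_switch,
                report21.age_at_pupation, report21.age_at_emergence]
        assert all(b > a for a, b in zip(ages, ages[1:])) or (
            # Phase II collapses to zero duration under abundant food
            report21.age_at_phase_switch == report21.age_at_pupation
        )
        assert report21.Lb <= report21.Lp <= report21.Lj

    def test_phase2_collapses_at_abundant_food(self, report21):
        """At f=1 the reserve density is already maximal when Phase II begins."""
        assert report21.age_at_pupation - report21.age_at_phase_switch < 0.02

    def test_event_trigger_residuals(self, sim21, params):
        """Relative trigger residuals below 1e-6 at each recorded event."""
        traj = sim21.trajectory
        # puberty: last immature sample sits at EH = EHp
        larva = traj[traj.stage.isin(["L1", "L2", "L3"])]
        assert larva.EH_J.iloc[-1] == pytest.approx(params.EHp, rel=1e-6)
        # phase switch: reproduction-buffer density at [ERj]
        p1 = traj[traj.stage == "L4_phase1"]
        assert p1.ER_J.iloc[-1] / p1.V_cm3.iloc[-1] == pytest.approx(
            params.ERj, rel=1e-6)
        # pupation: reserve density at [Em]
        assert p1.E_J.iloc[-1] / p1.V_cm3.iloc[-1] == pytest.approx(
            params.Em, rel=1e-6)
        # emergence: pupal maturity at EHe
        pupa = traj[traj.stage == "pupa"]
        assert pupa.EH_J.iloc[-1] == pytest.approx(params.EHe, rel=1e-6)

    def test_maturity_frozen_through_L4(self, sim21, params):
        l4 = sim21.trajectory[sim21.trajectory.stage.isin(["L4_phase1", "L4_phase2"])]
        assert np.allclose(l4.EH_J, params.EHp, rtol=1e-9)

    def test_buffer_frozen_after_phase_switch(self, sim21, params):
        traj = sim21.trajectory
        t_switch = sim21.report.age_at_birth + sim21.report.age_at_phase_switch
        after = traj[(traj.t_d >= t_switch) & (traj.stage != "imago")]
        ER_j = params.ERj * sim21.report.Vj
        assert np.allclose(after.ER_J, ER_j, rtol=1e-6)

    def test_v1_morph_growth_is_exponential(self, sim21):
        """ln V is affine in t during the immature instars at constant f."""
        traj = sim21.trajectory
        larva = traj[traj.stage.isin(["L1", "L2", "L3"])]
        t0 = larva.t_d.iloc[0]
        sel = larva[larva.t_d > t0 + 0.5]  # drop the short transient
        coeffs = np.polyfit(sel.t_d, np.log(sel.V_cm3), 1)
        resid = np.log(sel.V_cm3) - np.polyval(coeffs, sel.t_d)
        assert np.max(np.abs(resid)) < 0.01 * np.abs(np.log(sel.V_cm3)).mean()

    def test_weak_homeostasis_reserve_density_tracks_f(self, params):
        """Scaled reserve density converges to f during feeding growth."""
        res = simulate_lifecycle(
            params, ForcingScenario(T_celsius=21.0, f_constant=0.6),
            stop_after="pupation")
        traj = res.trajectory
        larva = traj[traj.stage.isin(["L1", "L2", "L3"])]
        e_end = larva.E_J.iloc[-1] / (params.Em * larva.V_cm3.iloc[-1])
        assert e_end == pytest.approx(0.6, rel=0.01)

    def test_seed_structure_insensitivity(self, params, scenario21, report21):
        res = simulate_lifecycle(params, scenario21, v_seed=0.5e-8)
        assert res.report.age_at_emergence == pytest.approx(
            report21.age_at_emergence, rel=0.005)

    def test_male_completes_with_lower_assimilation(self, params):
        res = simulate_lifecycle(
            params, ForcingScenario(T_celsius=21.0, f_constant=1.0, sex="male"))
        assert res.status == "completed"
        # lower {pAm} lowers [Em]: a smaller reserve must be accumulated but
        # growth is also slower; the cycle still completes with fewer eggs
        assert res.report.Ni > 0


class TestInstarPartition:
    def test_molts_partition_immature_phase(self, report21):
        d1 = report21.age_at_molt1
        d2 = report21.age_at_molt2 - report21.age_at_molt1
        d3 = report21.age_at_puberty - report21.age_at_molt2
        assert d1 > 0 and d2 > 0 and d3 > 0
        assert d1 + d2 + d3 == pytest.approx(report21.age_at_puberty, rel=1e-9)

    def test_equal_molt_constants_give_equal_length_ratios(self, sim21, params):
        # s1 = s2 implies the first two molt thresholds share one ratio
        traj = sim21.trajectory
        larva = traj[traj.stage.isin(["L1", "L2", "L3"])].reset_index(drop=True)
        L = np.interp(
            [sim21.report.age_at_molt1 + sim21.report.age_at_birth,
             sim21.report.age_at_molt2 + sim21.report.age_at_birth],
            larva.t_d, larva.V_cm3 ** (1 / 3))
        r1 = L[0] / sim21.report.Lb
        r2 = L[1] / L[0]
        assert r1 == pytest.approx(r2, rel=1e-3)
        assert r1 == pytest.approx(params.s1 ** 0.5, rel=1e-3)


class TestEnvironmentalResponses:
    def test_food_monotonicity(self, params):
        """Less food: later pupation/emergence, fewer eggs."""
        table = sweep_food(params, [0.4, 0.7, 1.0], stop_after="emergence")
        assert table.reached_pupation.all()
        assert (np.diff(table.age_at_pupation) <= 0).all()
        assert (np.diff(table.age_at_emergence) <= 0).all()
        assert (np.diff(table.Ni) >= 0).all()

    def test_temperature_monotonicity(self, params):
        table = sweep_temperature(params, [10, 15, 21, 25, 30], stop_after="emergence")
        assert (np.diff(table.age_at_emergence) < 0).all()

    def test_pure_time_scaling_with_temperature(self, params):
        """A single cT for all rates rescales the whole trajectory in time."""
        r21 = simulate_lifecycle(
            params, ForcingScenario(T_celsius=21.0, f_constant=1.0),
            stop_after="pupation").report
        r15 = simulate_lifecycle(
            params, ForcingScenario(T_celsius=15.0, f_constant=1.0),
            stop_after="pupation").report
        ratio = temperature_correction(294.15, params) / temperature_correction(
            288.15, params)
        assert r15.age_at_pupation == pytest.approx(
            r21.age_at_pupation * ratio, rel=1e-6)
        assert r15.Lj == pytest.approx(r21.Lj, rel=1e-8)  # lengths unaffected

    def test_unreachable_pupation_reported_not_raised(self, params):
        res = simulate_lifecycle(
            params,
            ForcingScenario(T_celsius=21.0, f_constant=0.05, horizon_days=40.0),
        )
        assert res.status in ("pupation_not_reached", "puberty_not_reached")
        assert math.isnan(res.report.age_at_pupation)

    def test_declining_food_prolongs_development(self, params):
        from chirodeb import declining_food_scenario

        base = simulate_lifecycle(
            params, ForcingScenario(T_celsius=21.0, f_constant=1.0),
            stop_after="pupation").report
        scen = declining_food_scenario(fmin=0.25, t_puberty=base.age_at_puberty)
        res = simulate_lifecycle(params, scen, stop_after="pupation")
        assert res.status == "completed"
        assert res.report.age_at_pupation > base.age_at_pupation
        assert res.report.age_at_puberty == pytest.approx(
            base.age_at_puberty, rel=1e-6)  # f = 1 until puberty


class TestDyarThresholdValidation:
    def test_thresholds_outside_immature_range_rejected(self, params, scenario21):
        # an extreme exponent pushes the second molt threshold past puberty
        with pytest.raises(ValueError, match="Dyar"):
            simulate_lifecycle(params, scenario21, stop_after="pupation",
                               dyar_exponent=2.0)

    def test_empty_sweep_grids_rejected(self, params):
        with pytest.raises(ValueError):
            sweep_food(params, [])
        with pytest.raises(ValueError):
            sweep_temperature(params, [])


class TestPupationTransition:
    def test_structure_conversion_bookkeeping(self, params):
        state = OrganismState(t=17.0, E=28.0, V=1e-3, EH=params.EHp,
                              ER=5.3, stage=Stage.L4_PHASE2, sM=4.5)
        pupa = pupation_transition(state, params, v_seed=1e-8)
        assert pupa.E == pytest.approx(28.0 + params.kappaV * params.EG * 1e-3)
        assert pupa.ER == state.ER        # the buffer is retained
        assert pupa.EH == 0.0             # maturity restarts from zero
        assert pupa.V == 1e-8
        assert pupa.sM == state.sM        # acceleration stays frozen
        # with the fitted kappaV the reserve credit is a negligible fraction
        assert params.kappaV * params.EG * 1e-3 < 1e-5 * params.EG * 1e-3


class TestEggNumber:
    def test_linear_in_structure_and_efficiency(self, params):
        n1 = egg_number(params, 5323.0, 1e-3, 0.02)
        assert egg_number(params, 5323.0, 2e-3, 0.02) == pytest.approx(2 * n1)
        zero = params.replace(kappaR=1e-12)
        assert egg_number(zero, 5323.0, 1e-3, 0.02) == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(ValueError):
            egg_number(params, 5323.0, 1e-3, 0.0)


class TestSurvival:
    def test_background_hazard_only_under_abundant_food(self, sim21, params):
        """With food ad libitum the only mortality is the background rate."""
        traj = sim21.trajectory
        t_birth = sim21.report.age_at_birth
        cT = temperature_correction(294.15, params)
        larva = traj[traj.stage.isin(["L1", "L2", "L3", "L4_phase1"])]
        expected = np.exp(-params.hb * cT * (larva.t_d - t_birth))
        assert np.allclose(larva.survival, expected, rtol=1e-6)

    def test_survival_monotone_and_starts_at_one(self, sim21):
        s = sim21.trajectory.survival.to_numpy()
        assert s[0] == pytest.approx(1.0)
        assert (np.diff(s) <= 1e-12).all()

    def test_starvation_accelerates_mortality(self, params):
        res = simulate_lifecycle(
            params,
            ForcingScenario(T_celsius=21.0, f_constant=0.0, horizon_days=30.0),
        )
        traj = res.trajectory
        t_birth = res.report.age_at_birth
        cT = temperature_correction(294.15, params)
        end = traj.iloc[-1]
        background = math.exp(-params.hb * cT * (end.t_d - t_birth))
        assert end.survival < background


class TestBruteForceOracle:
    def test_fixed_step_rk4_reproduces_puberty_age(self, params, report21):
        """A dumb fixed-step RK4 at dt = 1e-4 d agrees with the event solver."""
        E0, t_birth, birth = initial_reserve(params, 294.15)
        cT = temperature_correction(294.15, params)

        def rhs(y):
            E, V, EH = y
            sM = max(1.0, V ** (1 / 3) / birth.L)
            st = OrganismState(t=0, E=E, V=V, EH=EH, ER=0.0, stage=Stage.L1, sM=sM)
            p = compute_fluxes(st, 1.0, params, cT)
            return np.array([p.pA - p.pC, p.pG / params.EG, p.pR])

        y = np.array([birth.E, birth.V, birth.EH])
        t, dt = 0.0, 1e-4
        while y[2] < params.EHp:
            k1 = rhs(y)
            k2 = rhs(y + dt / 2 * k1)
            k3 = rhs(y + dt / 2 * k2)
            k4 = rhs(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        assert t == pytest.approx(report21.age_at_puberty, rel=1e-3)
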