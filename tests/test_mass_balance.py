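"""Mass-balance closure: evaluation, prediction, metrics, consistency."""

import warnings

import numpy as np
import pytest

import hmecalc as hc
from hmecalc import BreathMeasurement as BM
from hmecalc import Location

from conftest import GRID

COND = hc.GasConditions.from_celsius(38.0)
V_HALF = hc.volume_to_moles(0.5, COND)


# Frozen closed-form oracle values for the no-HME rig (ha 44 mg/l,
# hb 0, V_D 30 ml, 38 degC), computed by hand from
#   mb = (ha*V_D + hb*(V-V_D))/V,  V_sup = V*(1-mb)/(1-ha),
#   wo = (hb*V_D + ha*(V_sup-V_D))/V_sup
NO_HME_EXPECTED = {
    0.25: (5.280, 39.012),
    0.50: (2.640, 41.515),
    0.75: (1.760, 42.346),
}


class TestEvaluateFromMb:
    def test_zero_storage_identity(self, rig44):
        # mb*V_mb = ha*V_D with dry carrier gas leaves nothing for the HME
        mb = rig44.ha * rig44.dead_space / V_HALF
        state = hc.evaluate_from_mb(rig44, mb, V_HALF)
        assert state.m_st == 0.0

    def test_dead_space_exceeds_volume(self, rig44):
        with pytest.raises(hc.DeadSpaceError):
            hc.evaluate_from_mb(rig44, 0.01, hc.volume_to_moles(0.02, COND))

    def test_recovers_simulated_storage(self, grid_sims):
        for (eta, v, ha), res in grid_sims.items():
            led = res.steady_ledger()
            state = hc.evaluate_from_mb(res.params, led.mb, led.V_mb)
            assert state.m_st * 1e-3 == pytest.approx(led.m_st, rel=1e-9)
            assert state.eta == pytest.approx(eta, abs=0.01)

    def test_negative_storage_warns(self, rig44):
        # mb below the pure dead-space line implies a net-absorbing HME
        mb = 0.5 * rig44.ha * rig44.dead_space / V_HALF
        with pytest.warns(hc.NetAbsorptionWarning):
            state = hc.evaluate_from_mb(rig44, mb, V_HALF)
        assert state.m_st < 0

    def test_dead_space_ratio_warning(self, rig44):
        v_small = hc.volume_to_moles(0.1, COND)  # 30 ml dead space > 20%
        mb = rig44.ha * rig44.dead_space / v_small * 1.05
        with pytest.warns(hc.DeadSpaceRatioWarning):
            hc.evaluate_from_mb(rig44, mb, v_small)


class TestEvaluateFromWo:
    def test_no_hme_measurements_give_zero_storage(self, rig44):
        pred = hc.predict_no_hme(rig44, V_HALF)
        state = hc.evaluate_from_wo(rig44, pred.wo, pred.V_exp)
        assert abs(state.m_st) * 1e-3 < 1e-10

    def test_wo_at_target_without_dead_space(self):
        # an HME returning nothing and no dead space: expirate stays at ha
        params = hc.RigParameters.from_practical(dead_space_ml=0.0)
        state = hc.evaluate_from_wo(params, params.ha, V_HALF)
        assert abs(state.m_st) * 1e-3 < 1e-12
        assert state.m_add * 1e-3 == pytest.approx(params.ha * V_HALF, rel=1e-9)

    def test_agrees_with_mb_route(self, grid_sims):
        for res in grid_sims.values():
            led = res.steady_ledger()
            st_mb = hc.evaluate_from_mb(res.params, led.mb, led.V_mb)
            st_wo = hc.evaluate_from_wo(res.params, led.wo, led.V_exp)
            assert st_wo.m_st == pytest.approx(st_mb.m_st, rel=1e-6)

    def test_dead_space_error(self, rig44):
        with pytest.raises(hc.DeadSpaceError):
            hc.evaluate_from_wo(rig44, 0.02, rig44.dead_space * 0.5)


@pytest.fixture(scope="module")
def reference(rig44):
    state = hc.predict_with_hme(rig44, V_HALF, hc.HMEBehavior.linear(0.6))
    return rig44, state


class TestEvaluateDispatch:

    def test_all_six_combinations_agree(self, reference):
        params, st = reference
        concs = [
            BM(Location.P2_MOISTURE_BENEFIT, st.V_mb, st.mb),
            BM(Location.P4_WATER_OUTPUT, st.V_exp, st.wo),
        ]
        vols = [
            BM(Location.P1_INSPIRED, st.V_insp),
            BM(Location.P2_MOISTURE_BENEFIT, st.V_mb),
            BM(Location.P4_WATER_OUTPUT, st.V_exp),
        ]
        for cm in concs:
            for vm in vols:
                out = hc.evaluate(params, cm, vm)
                assert out.m_st == pytest.approx(st.m_st, rel=1e-8)
                assert out.V_insp == pytest.approx(st.V_insp, rel=1e-8)

    def test_concentration_at_p1_rejected(self, reference):
        params, st = reference
        with pytest.raises(hc.UsageError):
            hc.evaluate(
                params,
                BM(Location.P1_INSPIRED, st.V_insp, 0.001),
                BM(Location.P2_MOISTURE_BENEFIT, st.V_mb),
            )

    def test_volume_only_record_rejected_as_concentration(self, reference):
        params, st = reference
        with pytest.raises(hc.UsageError):
            hc.evaluate(
                params,
                BM(Location.P2_MOISTURE_BENEFIT, st.V_mb),
                BM(Location.P1_INSPIRED, st.V_insp),
            )


class TestPredictNoHme:
    @pytest.mark.parametrize("v_l", sorted(NO_HME_EXPECTED))
    def test_frozen_values(self, rig44, v_l):
        mb_exp, wo_exp = NO_HME_EXPECTED[v_l]
        pred = hc.predict_no_hme(rig44, hc.volume_to_moles(v_l, COND))
        assert pred.mb_mg_l == pytest.approx(mb_exp, abs=5e-3)
        assert pred.wo_mg_l == pytest.approx(wo_exp, abs=5e-3)

    def test_monotone_trends_and_volume_order(self, rig44):
        preds = [
            hc.predict_no_hme(rig44, hc.volume_to_moles(v, COND))
            for v in (0.25, 0.5, 0.75)
        ]
        mbs = [p.mb for p in preds]
        wos = [p.wo for p in preds]
        assert mbs[0] > mbs[1] > mbs[2]  # mb falls with tidal volume
        assert wos[0] < wos[1] < wos[2]  # wo rises with tidal volume
        assert all(p.V_exp > p.V_mb for p in preds)

    def test_no_dead_space_limit(self):
        params = hc.RigParameters.from_practical(dead_space_ml=0.0)
        pred = hc.predict_no_hme(params, V_HALF)
        assert pred.mb == params.hb
        assert pred.wo == pytest.approx(params.ha, rel=1e-14)

    def test_large_volume_limits(self, rig44):
        pred = hc.predict_no_hme(rig44, hc.volume_to_moles(50.0, COND))
        assert pred.mb < rig44.hb + 1e-4
        assert pred.wo == pytest.approx(rig44.ha, rel=1e-2)


class TestPredictWithHme:
    def test_fixed_zero_storage_equals_no_hme(self, rig44):
        base = hc.predict_no_hme(rig44, V_HALF)
        st = hc.predict_with_hme(rig44, V_HALF, hc.HMEBehavior.fixed_storage(0.0))
        assert st.mb == pytest.approx(base.mb, rel=1e-12)
        assert st.wo == pytest.approx(base.wo, rel=1e-12)

    def test_efficiency_round_trip(self, rig44):
        st = hc.predict_with_hme(rig44, V_HALF, hc.HMEBehavior.linear(0.6))
        back = hc.evaluate_from_mb(rig44, st.mb, st.V_mb)
        assert back.eta == pytest.approx(0.6, abs=1e-8)

    def test_infeasible_efficiency(self, rig44):
        with pytest.raises(hc.InfeasibleBehaviorError):
            hc.predict_with_hme(rig44, V_HALF, hc.HMEBehavior.linear(1.01))

    def test_performance_shifts_water_from_exp_to_mb(self, rig44):
        low = hc.predict_with_hme(rig44, V_HALF, hc.HMEBehavior.linear(0.1))
        high = hc.predict_with_hme(rig44, V_HALF, hc.HMEBehavior.linear(0.9))
        assert high.V_mb > low.V_mb
        assert high.V_exp < low.V_exp
        assert low.V_exp > low.V_mb  # base ordering ...
        assert high.V_mb > high.V_exp  # ... reverses for strong HMEs


class TestMetrics:
    def test_efficiency_zero_and_undefined(self, rig44):
        st = hc.predict_no_hme(rig44, V_HALF).state
        assert hc.efficiency(st) == 0.0
        degenerate = hc.RigParameters.from_practical(dead_space_ml=0.0)
        st0 = hc.predict_no_hme(degenerate, V_HALF).state
        # hb = 0 and V_D = 0: water in equals water out, eta undefined
        with pytest.raises(hc.EfficiencyUndefinedError):
            hc.efficiency(
                hc.MassBalanceState(
                    **{**{f: getattr(st0, f) for f in (
                        "m_i_ent", "m_st", "m_i_ext", "m_ret", "m_sup",
                        "m_e_ext", "m_add", "V_insp", "V_mb", "V_exp",
                        "V_sup", "c_ext", "eta")},
                       "m_e_ent": st0.m_i_ent, "conditions": st0.conditions}
                )
            )

    def test_water_load_approximation(self, rig44, grid_sims):
        assert hc.approximate_water_load(0.0, V_HALF).value_mmol == 0.0
        approx = hc.approximate_water_load(rig44.ha, V_HALF)
        assert approx.value_mmol == pytest.approx(rig44.ha * V_HALF * 1e3)
        for res in grid_sims.values():
            led = res.steady_ledger()
            state = hc.evaluate_from_mb(res.params, led.mb, led.V_mb)
            load = hc.approximate_water_load(res.params.ha, led.V_mb, state)
            assert load.relative_deviation < 0.10

    def test_published_performance_zero_case(self, rig44):
        mb_mg_l = hc.fraction_to_absolute(rig44.ha * rig44.dead_space / V_HALF, COND)
        out = hc.performance_from_published(mb_mg_l, 0.5, rig44)
        assert out.performance_mg_per_breath == pytest.approx(0.0, abs=1e-9)

    def test_published_performance_supersaturated_warns(self, rig44):
        with pytest.warns(hc.SupersaturationWarning):
            hc.performance_from_published(50.0, 0.5, rig44)

    def test_le_hme_with_humid_carrier_gas(self):
        # laryngectomy scenario: ambient air at 10 mg/l, mb-only access
        params = hc.RigParameters.from_practical(hb_mg_l=10.0)
        res = hc.simulate_rig(
            params, hc.HMEBehavior.linear(0.5),
            hc.FlowProfile(tidal_volume=0.5), n_breaths=14,
        )
        led = res.steady_ledger()
        out = hc.performance_from_published(
            hc.fraction_to_absolute(led.mb, COND),
            hc.moles_to_volume(led.V_mb, COND),
            params,
        )
        true_mg = led.m_st * hc.MOLAR_MASS_WATER * 1e3
        assert out.performance_mg_per_breath == pytest.approx(true_mg, rel=0.02)
        assert out.efficiency_percent == pytest.approx(50.0, abs=1.0)


@pytest.fixture(scope="module")
def full_set(grid_sims):
    res = grid_sims[(0.5, 0.5, 44.0)]
    led = res.steady_ledger()
    return res.params, led, [
        BM(Location.P2_MOISTURE_BENEFIT, led.V_mb, led.mb),
        BM(Location.P4_WATER_OUTPUT, led.V_exp, led.wo),
        BM(Location.P1_INSPIRED, led.V_insp),
    ]


class TestConsistencyResiduals:

    def test_consistent_data_has_tiny_residuals(self, full_set):
        params, _, measurements = full_set
        rep = hc.consistency_residuals(params, measurements)
        assert rep.max_storage_discrepancy <= 1e-8
        assert rep.max_identity_residual <= 1e-8
        assert rep.consistent

    def test_perturbed_wo_is_flagged(self, full_set):
        params, led, _ = full_set
        rep = hc.consistency_residuals(params, [
            BM(Location.P2_MOISTURE_BENEFIT, led.V_mb, led.mb),
            BM(Location.P4_WATER_OUTPUT, led.V_exp, led.wo * 1.05),
            BM(Location.P1_INSPIRED, led.V_insp),
        ])
        assert not rep.consistent
        assert rep.max_storage_discrepancy > 1e-3

    def test_minimal_pair_alone_is_rejected(self, full_set):
        params, led, _ = full_set
        with pytest.raises(hc.UsageError):
            hc.consistency_residuals(
                params, [BM(Location.P2_MOISTURE_BENEFIT, led.V_mb, led.mb)]
            )


class TestConservation:
    def test_identities_on_randomized_inputs(self):
        """The four circuit identities and dry-gas balance on random states."""
        rng = np.random.default_rng(2026)
        n_checked = 0
        for _ in range(300):
            ha_mg = rng.uniform(30.0, 46.0)
            hb_mg = rng.uniform(0.0, 12.0)
            vd_ml = rng.uniform(0.0, 60.0)
            v_l = rng.uniform(0.15, 1.0)
            params = hc.RigParameters.from_practical(
                ha_mg_l=ha_mg, hb_mg_l=hb_mg, dead_space_ml=vd_ml
            )
            v_mb = hc.volume_to_moles(v_l, COND)
            if v_mb <= params.dead_space:
                continue
            lo = params.ha * params.dead_space / v_mb  # zero-storage mb
            hi = 0.95 * (params.ha + (1 - params.ha) * 0.2)
            if lo >= hi:
                continue
            mb = rng.uniform(lo, hi)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                state = hc.evaluate_from_mb(params, mb, v_mb)
            for name, residual in state.identity_residuals().items():
                assert residual <= 1e-10, name
            n_checked += 1
        assert n_checked > 200

    def test_identities_on_predicted_states(self, rig44):
        for eta in (0.0, 0.3, 0.7):
            st = hc.predict_with_hme(rig44, V_HALF, hc.HMEBehavior.linear(eta))
            assert max(st.identity_residuals().values()) <= 1e-10


def test_rig_parameter_validation():
    with pytest.raises(hc.DomainError):
        hc.RigParameters(ha=0.02, hb=0.05, dead_space=0.001)  # hb > ha
    with pytest.raises(hc.DomainError):
        hc.RigParameters(ha=0.06, hb=0.0, dead_space=-0.1)


def test_behavior_validation():
    with pytest.raises(hc.InfeasibleBehaviorError):
        hc.HMEBehavior.linear(1.2)
    with pytest.raises(hc.UsageError):
        hc.HMEBehavior("quadratic")
    with pytest.raises(hc.DomainError):
        hc.HMEBehavior.asymptotic(0.5, shape=-1.0)
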