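"""Unit and property tests of the well-mixed circuit mass balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circlegas import (
    CircuitConfig,
    CircuitState,
    ConfigurationError,
    FreshGasSettings,
    GasComposition,
    PatientModel,
    StepSizeError,
    oxygen_delivery_ml_min,
    step,
    tau_conway,
    tau_simple,
    total_volume,
    wash_in_fraction,
)


class TestTotalVolume:
    @pytest.mark.parametrize(
        "vols, expected",
        [
            ((4.7, 1.5, 1.2, 1.2), 5.6),  # absorber swapped + hoses
            ((4.7, 1.5, 1.5, 0.0), 4.7),  # default absorber, no hoses
            ((5.0, 1.0, 2.0, 0.5), 6.5),
        ],
    )
    def test_component_accounting(self, vols, expected):
        cfg = CircuitConfig(*vols)
        assert total_volume(cfg) == pytest.approx(expected)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ConfigurationError):
            CircuitConfig(v_internal=1.0, v_absorber_default=2.0,
                          v_absorber_used=0.5, v_hose=0.1)


class TestWashIn:
    def test_starts_at_initial_value(self):
        assert wash_in_fraction(0.3, 0.9, 0.0, 2.0) == pytest.approx(0.3)

    def test_attains_63_percent_at_one_tau(self):
        # from zero, the value at t = tau is 63 % of the final value
        # to two significant figures
        frac = wash_in_fraction(0.0, 0.8, 2.5, 2.5) / 0.8
        assert frac == pytest.approx(0.63, abs=0.005)

    def test_two_tau_value(self):
        got = wash_in_fraction(0.21, 0.68, 4.0, 2.0)
        assert got == pytest.approx(0.21 + 0.47 * (1 - math.exp(-2)), abs=1e-12)
        assert got == pytest.approx(0.6164, abs=5e-4)

    @given(
        f0=st.floats(0, 1), f_del=st.floats(0, 1),
        t=st.floats(0, 100), tau=st.floats(0.01, 50),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_between_endpoints(self, f0, f_del, t, tau):
        v = wash_in_fraction(f0, f_del, t, tau)
        assert min(f0, f_del) - 1e-12 <= v <= max(f0, f_del) + 1e-12

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            wash_in_fraction(0.2, 0.8, 1.0, 0.0)


class TestTimeConstants:
    @pytest.mark.parametrize(
        "v, fgf, expected", [(5.6, 0.5, 11.2), (5.6, 2.0, 2.8), (1.0, 1.0, 1.0)]
    )
    def test_tau_simple(self, v, fgf, expected):
        assert tau_simple(v, fgf) == pytest.approx(expected)

    def test_tau_conway_examples(self):
        assert tau_conway(5.6, 1.0, 0.0) == pytest.approx(5.6)
        assert tau_conway(5.6, 1.0, 0.3) == pytest.approx(8.0)

    def test_tau_conway_reduces_to_simple_exactly(self):
        for v, fgf in [(5.6, 0.5), (4.7, 2.0), (1.0, 3.0)]:
            assert tau_conway(v, fgf, 0.0) == tau_simple(v, fgf)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            tau_conway(5.6, 0.5, 0.5)
        with pytest.raises(ValueError):
            tau_simple(5.6, 0.0)


class TestOxygenDelivery:
    def test_maintenance_mixture_bookkeeping(self):
        air = FreshGasSettings(0.5, GasComposition.from_delivery(68.0, 5.0, "n2"))
        n2o = FreshGasSettings(0.5, GasComposition.from_delivery(60.0, 3.5, "n2o"))
        assert oxygen_delivery_ml_min(air) == pytest.approx(340.0)
        assert oxygen_delivery_ml_min(n2o) == pytest.approx(300.0)


class TestStep:
    def test_no_flows_leaves_state_unchanged(self, default_config):
        fg = FreshGasSettings(0.0, GasComposition.room_air())
        patient = PatientModel(vo2=0, vco2=0)
        st0 = CircuitState(0.0, GasComposition(0.4, 0.02, 0.3, 0.0, 0.28))
        st1 = step(st0, 0.5, default_config, fg, patient)
        np.testing.assert_allclose(st1.comp.as_array(), st0.comp.as_array(), atol=1e-12)

    def test_matches_wash_in_closed_form(self, default_config, no_uptake_patient):
        """Constant settings, no uptake: trajectory matches the exponential
        wash-in equation, with first-order step-size convergence."""
        fg = FreshGasSettings(2.0, GasComposition.from_delivery(68.0, 5.0, "n2"))
        tau = tau_simple(default_config.v_tot, 2.0)

        def max_rel_err(dt):
            st = CircuitState(0.0, GasComposition.room_air())
            worst = 0.0
            for _ in range(int(round(10.0 / dt))):
                st = step(st, dt, default_config, fg, no_uptake_patient)
                exact = wash_in_fraction(0.21, 0.68, st.t, tau)
                worst = max(worst, abs(st.comp.fo2 - exact) / exact)
            return worst

        e_coarse = max_rel_err(1.0 / 240.0)
        e_fine = max_rel_err(1.0 / 480.0)
        assert e_coarse < 0.01
        assert e_fine <= 0.6 * e_coarse  # halving dt halves the error

    def test_pure_dilution_converges_to_room_air(self, no_uptake_patient):
        cfg = CircuitConfig(bag_connected=False, entrain_flow=2.0,
                            fgf_retained_fraction=0.0)
        fg = FreshGasSettings(1.0, GasComposition.from_delivery(68.0, 5.0, "n2"))
        st = CircuitState(0.0, GasComposition(0.6, 0.05, 0.0, 0.0, 0.35))
        for _ in range(240 * 30):  # 30 min
            st = step(st, 1.0 / 240.0, cfg, fg, no_uptake_patient)
        assert st.comp.fo2 == pytest.approx(0.21, abs=1e-3)
        assert st.comp.fsevo == pytest.approx(0.0, abs=1e-3)

    def test_uptake_exceeding_inflow_rejected(self, default_config):
        fg = FreshGasSettings(0.1, GasComposition.pure_oxygen())
        with pytest.raises(ConfigurationError):
            step(CircuitState(0.0, GasComposition.room_air()), 0.01,
                 default_config, fg, PatientModel(vo2=250.0))

    def test_fraction_driven_negative_raises_step_error(self, default_config):
        # huge dt + strong uptake of a nearly absent gas
        fg = FreshGasSettings(5.0, GasComposition.pure_oxygen())
        patient = PatientModel(vo2=0, sevo_uptake=400.0)
        st = CircuitState(0.0, GasComposition(0.2, 0.001, 0.0, 0.0, 0.799))
        with pytest.raises(StepSizeError):
            step(st, 1.0, default_config, fg, patient)

    @given(st.data())
    @settings(max_examples=60, derandomize=True)
    def test_conservation_under_random_flows(self, data):
        """Fractions stay non-negative and sum to one after any step."""
        raw = np.array([data.draw(st.floats(0.01, 1.0)) for _ in range(5)])
        comp = GasComposition.from_array(raw / raw.sum())
        fgf = data.draw(st.floats(0.3, 6.0))
        o2_pct = data.draw(st.floats(21.0, 100.0))
        sevo = data.draw(st.floats(0.0, 8.0))
        fg = FreshGasSettings(fgf, GasComposition.from_delivery(o2_pct, sevo, "n2"))
        patient = PatientModel(vo2=data.draw(st.floats(0.0, 200.0)))
        cfg = CircuitConfig(
            bag_connected=data.draw(st.booleans()),
            entrain_flow=data.draw(st.floats(0.0, 3.0)),
            fgf_retained_fraction=data.draw(st.floats(0.0, 1.0)),
        )
        state = CircuitState(0.0, comp)
        try:
            for _ in range(10):
                state = step(state, 1.0 / 240.0, cfg, fg, patient)
                arr = state.comp.as_array()
                assert arr.min() >= 0.0
                assert abs(arr.sum() - 1.0) <= 1e-9
        except ConfigurationError:
            pass  # uptake can exceed inflow for some draws; that is rejected

    def test_boundedness_convex_hull_without_uptake(self, no_uptake_patient):
        """With no uptake each fraction stays inside the convex hull of
        {initial, delivered, room air}."""
        cfg = CircuitConfig(bag_connected=False, entrain_flow=1.7,
                            fgf_retained_fraction=1.0)
        fg = FreshGasSettings(1.0, GasComposition.from_delivery(68.0, 5.0, "n2"))
        init = GasComposition(0.55, 0.03, 0.0, 0.0, 0.42)
        lo = np.minimum.reduce([init.as_array(), fg.delivered.as_array(),
                                GasComposition.room_air().as_array()])
        hi = np.maximum.reduce([init.as_array(), fg.delivered.as_array(),
                                GasComposition.room_air().as_array()])
        state = CircuitState(0.0, init)
        for _ in range(240 * 20):
            state = step(state, 1.0 / 240.0, cfg, fg, no_uptake_patient)
            arr = state.comp.as_array()
            assert np.all(arr >= lo - 1e-9) and np.all(arr <= hi + 1e-9)


class TestGasComposition:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GasComposition(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            GasComposition(-0.1, 0.0, 0.0, 0.0, 1.1)

    def test_delivery_balance_absorbs_residue(self):
        c = GasComposition.from_delivery(68.0, 5.0, "n2")
        assert c.fo2 == pytest.approx(0.68)
        assert c.fsevo == pytest.approx(0.05)
        assert c.fn2 == pytest.approx(0.27)
        assert sum(c.as_array()) == pytest.approx(1.0, abs=1e-12)
        d = GasComposition.from_delivery(60.0, 3.5, "n2o")
        assert d.fn2o == pytest.approx(0.365)
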