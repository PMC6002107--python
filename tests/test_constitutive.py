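"""Resistance and compliance constitutive laws: printed anchor values,
inverses and the analytic alveolar-compliance derivative."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import respsim as r


class TestResistances:
    @pytest.mark.parametrize("flow, mult, expected", [
        (0.0, 1.0, 20.0),       # laminar term only
        (+0.05, 10.0, 23.0),    # inspiration: multiplier inactive
        (-0.05, 10.0, 230.0),   # expiration with laryngeal braking
    ])
    def test_upper_airway_rohrer(self, params_high, flow, mult, expected):
        assert r.upper_airway_resistance(flow, params_high, mult) == \
            pytest.approx(expected)

    def test_upper_airway_rejects_bad_input(self, params_high):
        with pytest.raises(ValueError):
            r.upper_airway_resistance(math.nan, params_high)
        with pytest.raises(ValueError):
            r.upper_airway_resistance(0.1, params_high,
                                      expiratory_multiplier=0.5)

    @pytest.mark.parametrize("V_c, expected", [
        (2.5, 0.1), (1.25, 0.4), (0.25, 10.0),
    ])
    def test_collapsible_poiseuille(self, params_high, V_c, expected):
        assert r.collapsible_resistance(V_c, params_high) == \
            pytest.approx(expected)

    def test_small_airway_anchors(self, params_high):
        # R_s = R_s_d + R_s_m at residual volume, ~R_s_m at TLC
        assert r.small_airway_resistance(23.0, params_high) == \
            pytest.approx(32.0)
        assert r.small_airway_resistance(63.0, params_high) == \
            pytest.approx(20.0 * math.exp(-15.0) + 12.0, rel=1e-12)
        assert r.small_airway_resistance(43.0, params_high) == \
            pytest.approx(20.0 * math.exp(-7.5) + 12.0, rel=1e-12)

    def test_resistances_never_below_their_minima(self, params_high):
        flows = np.linspace(-1.0, 1.0, 201)
        assert np.all(r.upper_airway_resistance(flows, params_high, 10.0)
                      >= params_high.R_u_m)
        vols = np.linspace(0.01, 2.5, 201)
        assert np.all(r.collapsible_resistance(vols, params_high)
                      >= params_high.K_c)
        VA = np.linspace(23.0, 63.0, 201)
        assert np.all(r.small_airway_resistance(VA, params_high)
                      >= params_high.R_s_m)


class TestCompliantCurves:
    def test_collapsible_sigmoid_midpoint_and_asymptote(self, params_high):
        assert r.collapsible_volume(4.4, params_high) == pytest.approx(1.25)
        assert r.collapsible_volume(1e4, params_high) == pytest.approx(2.5)

    def test_chest_wall_relaxation_volume(self, params_high):
        # softplus passes through V0 = 35 ml at zero recoil
        assert r.chest_wall_volume(0.0, params_high) == pytest.approx(35.0)

    def test_chest_wall_lower_asymptote(self, params_high):
        assert r.chest_wall_volume(-40.0, params_high) == \
            pytest.approx(23.0, abs=1e-10)

    @pytest.mark.parametrize("P", [-10.0, 0.0, 4.4, 20.0])
    def test_collapsible_round_trip(self, params_high, P):
        V = r.collapsible_volume(P, params_high)
        assert r.collapsible_pressure(V, params_high) == \
            pytest.approx(P, rel=1e-10, abs=1e-10)

    @pytest.mark.parametrize("V", [23.5, 30.0, 40.0])
    def test_chest_wall_round_trip(self, params_high, V):
        P = r.chest_wall_pressure(V, params_high)
        assert r.chest_wall_volume(P, params_high) == pytest.approx(
            V, rel=1e-10)

    @given(P=st.floats(-15.0, 30.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_identity_property(self, params_low, P):
        V_c = r.collapsible_volume(P, params_low)
        assert r.collapsible_pressure(V_c, params_low) == pytest.approx(
            P, rel=1e-10, abs=1e-8)
        V_cw = r.chest_wall_volume(P, params_low)
        if V_cw > params_low.RV + 1e-9:
            assert r.chest_wall_pressure(V_cw, params_low) == pytest.approx(
                P, rel=1e-10, abs=1e-8)

    def test_inverse_domain_errors(self, params_high):
        with pytest.raises(ValueError):
            r.collapsible_pressure(2.5, params_high)
        with pytest.raises(ValueError):
            r.collapsible_pressure(0.0, params_high)
        with pytest.raises(ValueError):
            r.chest_wall_pressure(23.0, params_high)

    def test_chest_wall_volume_always_above_rv(self, params_high):
        P = np.linspace(-60.0, 40.0, 501)
        assert np.all(r.chest_wall_volume(P, params_high)
                      >= params_high.RV)


class TestLungCurve:
    def test_recruited_fraction_anchors(self, rec):
        assert r.recruited_fraction(0.0, rec) == pytest.approx(0.01)
        assert r.recruited_fraction(1e3, rec) == pytest.approx(rec.gamma)
        assert r.recruited_fraction(rec.c_F, rec) == pytest.approx(
            (rec.alpha + rec.gamma) / 2.0)

    def test_recruited_fraction_increasing(self, rec):
        # strictly increasing over the operating range; saturates to gamma
        # (within float precision) far above the opening pressure
        P = np.linspace(0.0, 8.0, 401)
        assert np.all(np.diff(r.recruited_fraction(P, rec)) > 0)
        P = np.linspace(0.0, 40.0, 401)
        assert np.all(np.diff(r.recruited_fraction(P, rec)) >= 0)

    def test_lung_volume_anchors(self, params_high, rec):
        assert r.lung_volume(0.0, params_high, rec) == pytest.approx(23.0)
        assert r.lung_volume(1e3, params_high, rec) == pytest.approx(63.0)
        # near the high-compliance resting pressure the curve sits at the
        # published functional residual capacity
        assert 24.9 <= r.lung_volume(0.954, params_high, rec) <= 25.2

    def test_alveolar_compliance_at_zero(self, params_high, rec):
        # second term vanishes because the distension factor is zero
        assert r.alveolar_compliance(0.0, params_high, rec) == \
            pytest.approx(40.0 * 0.07 * 0.01, rel=1e-12)

    @pytest.mark.parametrize("P", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_alveolar_compliance_matches_finite_difference(
            self, params_high, rec, P):
        h = 1e-4
        fd = (r.lung_volume(P + h, params_high, rec)
              - r.lung_volume(P - h, params_high, rec)) / (2 * h)
        assert r.alveolar_compliance(P, params_high, rec) == \
            pytest.approx(fd, rel=1e-6)

    def test_alveolar_compliance_positive_on_grid(self, params_high, rec):
        P = np.arange(0.0, 40.0 + 1e-9, 0.1)
        assert np.all(r.alveolar_compliance(P, params_high, rec) > 0)
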