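"""Diverter reduced-order model: occlusion law, thresholds, switching,
characteristic time."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluidvent import (
    ConfigurationError,
    DiverterConfig,
    GeometryParameters,
    Phase,
    ScrewSettings,
    characteristic_time,
    lung_flow,
    next_phase,
    occlusion_to_resistance,
    switching_thresholds,
)


class TestOcclusionLaw:
    def test_fully_open_gives_base_resistance(self):
        assert occlusion_to_resistance(0.0, 10.0, 10.0) == 10.0

    def test_half_occluded(self):
        assert occlusion_to_resistance(0.5, 10.0, 10.0) == pytest.approx(15.0)

    def test_fully_closed_is_finite(self):
        r = occlusion_to_resistance(1.0, 10.0, 10.0)
        assert math.isfinite(r) and r == pytest.approx(20.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        d=st.tuples(st.floats(0, 1), st.floats(0, 1)).filter(lambda p: p[0] != p[1]),
        r_open=st.floats(1, 100),
        r_span=st.floats(1, 100),
    )
    def test_strictly_increasing(self, d, r_open, r_span):
        d1, d2 = sorted(d)
        assert occlusion_to_resistance(d1, r_open, r_span) < occlusion_to_resistance(
            d2, r_open, r_span
        )

    @pytest.mark.parametrize("d", [-0.1, 1.1])
    def test_domain_error(self, d):
        with pytest.raises(ConfigurationError):
            occlusion_to_resistance(d, 10.0, 10.0)


class TestSwitchingThresholds:
    def test_calibrated_midpoints_give_20_8(self):
        p_high, p_low = switching_thresholds(ScrewSettings(), DiverterConfig())
        assert p_high == pytest.approx(20.0)
        assert p_low == pytest.approx(8.0)

    def test_closing_sc_raises_pip(self):
        cfg = DiverterConfig()
        highs = [
            switching_thresholds(ScrewSettings(d_SC=d), cfg)[0]
            for d in (0.0, 0.5, 1.0)
        ]
        assert highs[0] < highs[1] < highs[2]

    def test_closing_fc_lowers_pip(self):
        cfg = DiverterConfig()
        highs = [
            switching_thresholds(ScrewSettings(d_FC=d), cfg)[0]
            for d in (0.0, 0.5, 1.0)
        ]
        assert highs[0] > highs[1] > highs[2]

    def test_degenerate_threshold_map_rejected_at_config_load(self):
        # a map whose corners collapse P_high below P_low cannot oscillate
        with pytest.raises(ConfigurationError, match="no oscillation"):
            DiverterConfig(P_high_base=9.0, k_FC=8.0)

    @settings(derandomize=True, max_examples=50)
    @given(d_fc=st.floats(0, 1), d_sc=st.floats(0, 1))
    def test_hysteresis_band_exists_for_all_admissible_screws(self, d_fc, d_sc):
        p_high, p_low = switching_thresholds(
            ScrewSettings(d_FC=d_fc, d_SC=d_sc), DiverterConfig()
        )
        assert p_high > p_low


class TestNextPhase:
    @pytest.mark.parametrize(
        "phase, p_alv, expected",
        [
            (Phase.INSPIRATION, 20.0, Phase.EXPIRATION),   # hit PIP
            (Phase.INSPIRATION, 19.99, Phase.INSPIRATION),
            (Phase.EXPIRATION, 10.0, Phase.EXPIRATION),    # inside the band
            (Phase.EXPIRATION, 8.0, Phase.INSPIRATION),    # hit PEEP
            (Phase.EXPIRATION, 25.0, Phase.EXPIRATION),
            (Phase.INSPIRATION, 5.0, Phase.INSPIRATION),
        ],
    )
    def test_switching_rule(self, phase, p_alv, expected):
        assert next_phase(phase, p_alv, 20.0, 8.0) is expected

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.floats(8.001, 19.999),
        phase=st.sampled_from([Phase.INSPIRATION, Phase.EXPIRATION]),
    )
    def test_idempotent_inside_hysteresis_band(self, p, phase):
        assert next_phase(phase, p, 20.0, 8.0) is phase

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            next_phase(Phase.INSPIRATION, 10.0, 8.0, 20.0)


class TestLungFlow:
    def test_inspiration_is_constant_flow(self):
        cfg = DiverterConfig(eta_insp=0.8, Q_src=0.5)
        q = lung_flow(Phase.INSPIRATION, 12.0, ScrewSettings(), cfg)
        assert q == pytest.approx(0.4)
        # independent of pressure
        assert lung_flow(Phase.INSPIRATION, 19.0, ScrewSettings(), cfg) == q

    def test_expiration_ohm_analog(self):
        q = lung_flow(
            Phase.EXPIRATION, 20.0, ScrewSettings(), DiverterConfig(), R_exp=100.0
        )
        assert q == pytest.approx(-0.2)

    def test_no_driving_pressure_no_flow(self):
        q = lung_flow(
            Phase.EXPIRATION, 0.0, ScrewSettings(), DiverterConfig(), R_exp=100.0
        )
        assert q == 0.0


class TestCharacteristicTime:
    def test_reference_geometry_and_flow(self):
        # 88 mm x 2.4 mm chamber filled at 30 L/min = 5e-4 m^3/s
        geom = GeometryParameters(D=0.088, h=0.0024)
        dt_c = characteristic_time(geom, volumetric_flow=5e-4)
        assert dt_c == pytest.approx(0.0292, abs=2e-4)

    def test_matches_volume_over_flow(self):
        geom = GeometryParameters()
        q = 3.3e-4
        assert characteristic_time(geom, volumetric_flow=q) == pytest.approx(
            math.pi * geom.D**2 * geom.h / 4.0 / q, rel=1e-14
        )

    def test_mass_flow_form_equals_volumetric_form(self):
        geom = GeometryParameters()
        v, mdot = 0.83, 6e-4  # air-like specific volume, m^3/kg
        assert characteristic_time(geom, v=v, mdot=mdot) == pytest.approx(
            characteristic_time(geom, volumetric_flow=v * mdot), rel=1e-14
        )

    @settings(derandomize=True, max_examples=30)
    @given(
        D=st.floats(0.01, 0.2), h=st.floats(0.001, 0.01),
        v=st.floats(0.5, 1.0), mdot=st.floats(1e-4, 1e-2),
    )
    def test_scaling_laws(self, D, h, v, mdot):
        base = characteristic_time(GeometryParameters(D=D, h=h), v=v, mdot=mdot)
        # quadratic in D, linear in h, inverse in mass flow
        assert characteristic_time(
            GeometryParameters(D=2 * D, h=h), v=v, mdot=mdot
        ) == pytest.approx(4 * base, rel=1e-12)
        assert characteristic_time(
            GeometryParameters(D=D, h=2 * h), v=v, mdot=mdot
        ) == pytest.approx(2 * base, rel=1e-12)
        assert characteristic_time(
            GeometryParameters(D=D, h=h), v=v, mdot=mdot / 2
        ) == pytest.approx(2 * base, rel=1e-12)

    def test_non_positive_arguments_rejected(self):
        with pytest.raises(ConfigurationError):
            characteristic_time(GeometryParameters(), v=0.8, mdot=0.0)
        with pytest.raises(ConfigurationError):
            characteristic_time(GeometryParameters(), volumetric_flow=-1e-4)
        with pytest.raises(ConfigurationError):
            GeometryParameters(D=-0.1)
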