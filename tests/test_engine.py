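"""Hybrid integrator: oracle agreement, conservation, events, determinism."""

import dataclasses

import numpy as np
import pytest

from fluidvent import (
    ConfigurationError,
    DiverterConfig,
    NonOscillationError,
    Phase,
    SimulationConfig,
    compute_metrics,
    estimate_period,
    expiration_closed_form,
    lung_preset,
    occlusion_to_resistance,
    segment_breaths,
    simulate,
)


def _expiration_segment(record):
    """Times/pressures of the first steady expiration (between switches)."""
    sw = record.switch_times
    t_exp = next(t for t, ph in sw[2:] if ph is Phase.EXPIRATION)
    t_insp = next(t for t, ph in sw if ph is Phase.INSPIRATION and t > t_exp)
    # the sample AT the switch instant carries the pre-switch (inspiratory)
    # state; the discharge starts strictly after it
    sel = (record.t > t_exp) & (record.t <= t_insp)
    return record.t[sel], record.P_alv[sel]


class TestIntegratorAccuracy:
    def test_expiration_matches_closed_form_oracle(self, healthy_config,
                                                   default_record):
        """The simulated expiration is an RC discharge; at dt = 1 ms the
        integrator must track the exact exponential to 0.01 cmH2O."""
        t_seg, p_seg = _expiration_segment(default_record)
        cfg = healthy_config
        r_exp = occlusion_to_resistance(
            cfg.screws.d_EC, cfg.diverter.R_EC_open, cfg.diverter.R_EC_span
        ) + cfg.lung.R_aw
        oracle = expiration_closed_form(p_seg[0], r_exp, cfg.lung, t_seg - t_seg[0])
        assert float(np.max(np.abs(p_seg - oracle))) <= 0.01

    def test_closed_form_endpoints(self, healthy_config):
        lung = healthy_config.lung
        assert expiration_closed_form(18.0, 120.0, lung, 0.0) == pytest.approx(18.0)
        tau = 120.0 * lung.C
        assert expiration_closed_form(18.0, 120.0, lung, tau) == pytest.approx(
            18.0 * np.exp(-1.0)
        )

    def test_volume_conservation(self, healthy_config, default_record):
        rec = default_record
        v_trapz = np.concatenate(
            [[0.0], np.cumsum(np.diff(rec.t) * 0.5 * (rec.Q[1:] + rec.Q[:-1]))]
        )
        bound = 10.0 * healthy_config.dt * float(np.max(np.abs(rec.Q)))
        assert float(np.max(np.abs(rec.V - v_trapz))) <= bound

    def test_volume_never_meaningfully_negative(self, default_record):
        assert float(np.min(default_record.V)) >= -1e-9

    def test_grid_refinement_changes_metrics_below_half_percent(self, healthy_config):
        metrics = []
        for dt in (0.001, 0.0005):
            cfg = dataclasses.replace(healthy_config, dt=dt, duration=30.0)
            m = compute_metrics(segment_breaths(simulate(cfg)), discard=2)
            metrics.append((m.PIP_mean, m.PEEP_mean, m.period_mean))
        for coarse, fine in zip(*metrics):
            assert abs(coarse - fine) / fine < 0.005


class TestEventHandling:
    def test_phases_strictly_alternate(self, default_record):
        phases = [ph for _, ph in default_record.switch_times]
        assert all(a is not b for a, b in zip(phases, phases[1:]))

    def test_switch_times_nondecreasing_and_in_range(self, default_record):
        times = [t for t, _ in default_record.switch_times]
        assert times == sorted(times)
        assert times[0] == 0.0 and times[-1] <= default_record.t[-1]

    def test_time_axis_strictly_increasing(self, default_record):
        assert float(np.min(np.diff(default_record.t))) > 0.0

    def test_pressure_at_switches_hits_thresholds(self, default_record):
        """Event refinement lands the recorded sample on the threshold."""
        rec = default_record
        for t_sw, new_phase in rec.switch_times[1:]:
            i = int(np.searchsorted(rec.t, t_sw))
            target = 8.0 if new_phase is Phase.INSPIRATION else 20.0
            assert rec.P_alv[i] == pytest.approx(target, abs=5e-3)

    def test_phase_labels_change_only_at_switch_times(self, default_record):
        rec = default_record
        change_idx = np.nonzero(rec.phase[1:] != rec.phase[:-1])[0]
        sw = np.array([t for t, _ in rec.switch_times[1:]])
        # the sample at a switch carries the outgoing phase; the next one flips
        assert len(change_idx) == len(sw)
        np.testing.assert_allclose(rec.t[change_idx], sw, atol=1e-9)


class TestDeterminismAndStability:
    def test_bit_identical_reruns(self, healthy_config, default_record):
        again = simulate(healthy_config)
        for name in ("t", "P_alv", "P_pl", "Q", "V"):
            assert np.array_equal(getattr(again, name), getattr(default_record, name))
        assert again.switch_times == default_record.switch_times

    def test_steady_period_variation_below_1e3(self, default_metrics):
        assert default_metrics.period_sd / default_metrics.period_mean < 1e-3

    def test_estimate_matches_simulated_period(self, healthy_config, default_metrics):
        assert estimate_period(healthy_config) == pytest.approx(
            default_metrics.period_mean, rel=0.01
        )


class TestDiagnostics:
    def test_unpowered_system_raises_non_oscillation(self, healthy_config):
        cfg = dataclasses.replace(
            healthy_config,
            diverter=dataclasses.replace(healthy_config.diverter, Q_src=0.0),
            duration=20.0,
        )
        with pytest.raises(NonOscillationError, match="eta_insp"):
            simulate(cfg)

    def test_unreachable_threshold_diagnosed(self, healthy_config):
        # an enormous high threshold is never reached by the finite source flow
        div = dataclasses.replace(healthy_config.diverter, P_high_base=1e4)
        cfg = dataclasses.replace(healthy_config, diverter=div, duration=20.0)
        with pytest.raises(NonOscillationError):
            simulate(cfg)

    def test_duration_shorter_than_ten_steps_rejected(self):
        with pytest.raises(ConfigurationError, match="duration"):
            SimulationConfig(dt=0.01, duration=0.05)

    def test_other_lung_presets_oscillate(self):
        # fibrosis (stiff) and emphysema (compliant) both sustain cycles
        for name in ("fibrosis", "emphysema"):
            cfg = SimulationConfig(lung=lung_preset(name), duration=30.0)
            cycles = segment_breaths(simulate(cfg))
            assert len(cycles) >= 2
            m = compute_metrics(cycles, discard=2)
            assert m.PIP_mean == pytest.approx(20.0, abs=0.05)
            assert m.PEEP_mean == pytest.approx(8.0, abs=0.05)
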