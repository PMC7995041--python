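"""Time integration of the coupled diverter-lung-trigger system.

The closed loop is a hybrid (switched) dynamical system.  Within a phase
the dynamics are a scalar linear ODE in the lung volume V:

* INSPIRATION: dV/dt = eta_insp * Q_src (constant-flow charging), so
  alveolar pressure rises linearly;
* EXPIRATION: dV/dt = -(V/C + P_peep + P_pl) / R_exp, an RC discharge
  through the total expiratory resistance R_exp = R_EC(d_EC) + R_aw, so
  alveolar pressure relaxes exponentially toward atmosphere with time
  constant R_exp * C.

Alveolar pressure is algebraic (the Windkessel expression), not a state;
only V is integrated.  Phase switches occur when P_alv crosses the
hysteresis thresholds; the crossing time is refined by bisection to
within dt/100 and the pre-switch state is recorded exactly at the
crossing, so downstream segmentation sees PIP and PEEP at the switch
instants to event-location accuracy.  The integrator is a fixed-step
explicit midpoint (RK2) scheme: the system is piecewise linear and
non-stiff at these parameters, and a fixed deterministic scheme makes
reruns bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, NonOscillationError
from .lung import LungParameters, alveolar_pressure
from .oscillator import (
    DiverterConfig,
    Phase,
    ScrewSettings,
    occlusion_to_resistance,
    switching_thresholds,
)
from .trigger import TriggerSchedule

__all__ = [
    "SimulationConfig",
    "WaveformRecord",
    "simulate",
    "expiration_closed_form",
    "estimate_period",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of one simulation run."""

    lung: LungParameters = field(default_factory=LungParameters)
    diverter: DiverterConfig = field(default_factory=DiverterConfig)
    screws: ScrewSettings = field(default_factory=ScrewSettings)
    trigger: TriggerSchedule = field(default_factory=TriggerSchedule)
    dt: float = 0.001
    duration: float = 60.0
    transient_discard: int = 2

    def __post_init__(self) -> None:
        if not self.dt > 0.0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if not self.duration >= 10.0 * self.dt:
            raise ConfigurationError(
                f"duration must be >= 10*dt = {10 * self.dt}, got {self.duration}"
            )
        if self.transient_discard < 0:
            raise ConfigurationError(
                f"transient_discard must be >= 0, got {self.transient_discard}"
            )


@dataclass
class WaveformRecord:
    """Time-indexed simulation output.

    Arrays share one length; ``t`` is strictly increasing.  A sample is
    recorded at every integration step and additionally at each refined
    switch time carrying the *pre-switch* state and phase label, so phase
    labels change only across recorded ``switch_times``.  ``switch_times``
    is a list of ``(time, new_phase)`` pairs and begins with the initial
    phase at t = 0.
    """

    t: np.ndarray
    P_alv: np.ndarray
    P_pl: np.ndarray
    Q: np.ndarray
    V: np.ndarray
    phase: np.ndarray
    switch_times: list[tuple[float, Phase]]

    def __len__(self) -> int:
        return len(self.t)


def expiration_closed_form(
    P_start: float,
    R_exp: float,
    lung: LungParameters,
    t: float | np.ndarray,
    P_inf: float = 0.0,
):
    """Exact alveolar pressure of an undisturbed expiration (oracle).

    With constant total expiratory resistance ``R_exp`` and no patient
    effort, the expiration phase is a linear RC discharge: alveolar
    pressure relaxes from ``P_start`` toward the asymptote ``P_inf``
    (atmosphere by default) with time constant ``R_exp * C``:

        P_alv(t) = P_inf + (P_start - P_inf) * exp(-t / (R_exp * C))
    """
    tau = R_exp * lung.C
    return P_inf + (P_start - P_inf) * np.exp(-np.asarray(t, dtype=float) / tau)


def estimate_period(config: SimulationConfig) -> float:
    """Analytic estimate of the steady oscillation period, s.

    Used for the non-oscillation watchdog and as a sanity figure; the
    simulated period differs only by event-location error.  Infinite
    components (e.g. zero source flow) are capped at the run duration.
    """
    lung = config.lung
    div = config.diverter
    p_high, p_low = switching_thresholds(config.screws, div)
    r_ec = occlusion_to_resistance(config.screws.d_EC, div.R_EC_open, div.R_EC_span)
    r_exp = r_ec + lung.R_aw
    q_i = div.eta_insp * div.Q_src

    cap = config.duration
    if q_i > 0.0:
        # steady start-of-inspiration state: P_alv = P_low at the switch
        v_start_over_c = p_low * r_exp / r_ec - lung.P_peep_base
        v_end_over_c = p_high - q_i * lung.R_aw - lung.P_peep_base
        t_i = lung.C * (v_end_over_c - v_start_over_c) / q_i
        t_i = min(max(t_i, 0.0), cap)
    else:
        t_i = cap
    p_exp_start = (p_high - q_i * lung.R_aw) * r_ec / r_exp
    if p_exp_start > p_low > 0.0:
        t_e = min(r_exp * lung.C * math.log(p_exp_start / p_low), cap)
    else:
        t_e = cap
    return t_i + t_e


def simulate(config: SimulationConfig) -> WaveformRecord:
    """Integrate the coupled system over ``[0, duration]``.

    Raises
    ------
    ConfigurationError
        Propagated from any invalid parameter block.
    NonOscillationError
        If no phase switch occurs within ten estimated periods, or the
        run completes without a full cycle; the message names the
        violated condition.
    """
    lung = config.lung
    div = config.diverter
    screws = config.screws
    schedule = config.trigger.resolve_tau(lung) if config.trigger.enabled else config.trigger

    p_high, p_low = switching_thresholds(screws, div)
    r_ec = occlusion_to_resistance(screws.d_EC, div.R_EC_open, div.R_EC_span)
    r_exp = r_ec + lung.R_aw
    q_insp = div.eta_insp * div.Q_src

    dt = config.dt
    duration = config.duration
    c = lung.C
    r_aw = lung.R_aw
    p_peep = lung.P_peep_base
    amp = schedule.amplitude if schedule.enabled else 0.0
    tau_tr = schedule.tau_s if (schedule.enabled and schedule.tau_s) else 1.0

    effort_times = list(schedule.effort_times(duration))
    effort_idx = 0
    effort_start: float | None = None

    period_est = estimate_period(config)
    watchdog = 10.0 * period_est

    def p_pl_at(t: float) -> float:
        if effort_start is None or amp == 0.0:
            return 0.0
        return -amp * (1.0 - math.exp(-(t - effort_start) / tau_tr))

    def flow(t: float, v: float, phase: Phase) -> float:
        if phase is Phase.INSPIRATION:
            return q_insp
        return -(v / c + p_peep + p_pl_at(t)) / r_exp

    def rk2(t: float, v: float, h: float, phase: Phase) -> float:
        k1 = flow(t, v, phase)
        k2 = flow(t + 0.5 * h, v + 0.5 * h * k1, phase)
        return v + h * k2

    def observables(t: float, v: float, phase: Phase) -> tuple[float, float, float]:
        p_pl = p_pl_at(t)
        q = flow(t, v, phase)
        return alveolar_pressure(lung, q, v, p_pl), p_pl, q

    def crossed(p_alv: float, phase: Phase) -> bool:
        if phase is Phase.INSPIRATION:
            return p_alv >= p_high
        return p_alv <= p_low

    t = 0.0
    v = 0.0
    phase = Phase.INSPIRATION
    t_last_switch = 0.0
    n_switches = 0

    ts: list[float] = []
    p_alvs: list[float] = []
    p_pls: list[float] = []
    qs: list[float] = []
    vs: list[float] = []
    phases: list[str] = []
    switch_times: list[tuple[float, Phase]] = [(0.0, phase)]

    def record(t_: float, v_: float) -> None:
        p_alv, p_pl, q = observables(t_, v_, phase)
        ts.append(t_)
        p_alvs.append(p_alv)
        p_pls.append(p_pl)
        qs.append(q)
        vs.append(v_)
        phases.append(phase.value)

    record(t, v)

    tol_t = dt / 100.0
    eps = 1e-12

    while t < duration - eps:
        # activate or skip scheduled efforts whose time has passed
        while effort_idx < len(effort_times) and effort_times[effort_idx] <= t + eps:
            if phase is Phase.EXPIRATION and effort_start is None:
                effort_start = effort_times[effort_idx]
            effort_idx += 1

        h = min(dt, duration - t)
        v_new = rk2(t, v, h, phase)
        p_alv_new, _, _ = observables(t + h, v_new, phase)

        if crossed(p_alv_new, phase):
            # bisect the step for the crossing time
            lo, hi = 0.0, h
            while hi - lo > tol_t:
                mid = 0.5 * (lo + hi)
                v_mid = rk2(t, v, mid, phase)
                p_mid, _, _ = observables(t + mid, v_mid, phase)
                if crossed(p_mid, phase):
                    hi = mid
                else:
                    lo = mid
            t_sw = t + hi
            v_sw = rk2(t, v, hi, phase)
            record(t_sw, v_sw)  # pre-switch sample at the crossing
            phase = phase.other()
            if phase is Phase.INSPIRATION:
                effort_start = None  # effort answered: pleural pressure resets
            switch_times.append((t_sw, phase))
            t_last_switch = t_sw
            n_switches += 1
            t, v = t_sw, v_sw
            continue

        t = t + h
        v = v_new
        record(t, v)

        if t - t_last_switch > watchdog:
            raise _diagnose(phase, p_alv_new, p_high, p_low, q_insp, period_est)

    if n_switches < 2:
        raise _diagnose(phase, p_alvs[-1], p_high, p_low, q_insp, period_est)

    return WaveformRecord(
        t=np.array(ts),
        P_alv=np.array(p_alvs),
        P_pl=np.array(p_pls),
        Q=np.array(qs),
        V=np.array(vs),
        phase=np.array(phases),
        switch_times=switch_times,
    )


def _diagnose(
    phase: Phase,
    p_alv: float,
    p_high: float,
    p_low: float,
    q_insp: float,
    period_est: float,
) -> NonOscillationError:
    if phase is Phase.INSPIRATION:
        if q_insp <= 0.0:
            reason = (
                f"delivered inspiratory flow eta_insp*Q_src = {q_insp} L/s: "
                "alveolar pressure cannot rise to P_high"
            )
        else:
            reason = (
                f"alveolar pressure ({p_alv:.3g} cmH2O) never reached "
                f"P_high = {p_high:.3g} cmH2O"
            )
    else:
        reason = (
            f"alveolar pressure ({p_alv:.3g} cmH2O) never fell to "
            f"P_low = {p_low:.3g} cmH2O"
        )
    return NonOscillationError(
        f"no sustained oscillation (estimated period {period_est:.3g} s): {reason}"
    )
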