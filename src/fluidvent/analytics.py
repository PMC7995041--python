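"""Breath segmentation and respiratory-index extraction.

Turns a pressure/flow waveform into per-cycle indices -- PIP, PEEP,
inspiratory and expiratory durations, period, respiratory rate, I:E
ratio and tidal volume -- and aggregates them as mean +/- SD.  Also
provides the exhaust-screw parameter sweep (period tuning curve) and the
ordinary-least-squares fit of period against screw depth.

Conventions
-----------
* PEEP is the pressure at the expiration-to-inspiration switch (truly
  end-expiratory), not the cycle minimum: a patient-effort dip can
  undercut the end-expiratory level, and PEEP is an end-expiratory
  concept.
* The I:E ratio is reported as the scalar x = T_e / T_i, read "1:x".
* Cycles during which a patient effort was active are flagged
  ``triggered`` and excluded from steady-state statistics unless
  explicitly requested, since triggered cycles are a separate regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress

from .errors import ConfigurationError, InsufficientDataError
from .engine import SimulationConfig, WaveformRecord, simulate
from .oscillator import Phase, ScrewSettings

__all__ = [
    "BreathCycle",
    "RespiratoryMetrics",
    "segment_breaths",
    "segment_pressure_trace",
    "compute_metrics",
    "ec_sweep",
    "fit_period_vs_depth",
    "PeriodDepthFit",
]

#: Bare-trace peak detection: minimum peak/trough separation (s) and
#: prominence as a fraction of the trace range.
_MIN_PEAK_SPACING_S = 0.5
_PROMINENCE_FRACTION = 0.10


@dataclass(frozen=True)
class BreathCycle:
    """Indices of one respiratory cycle (inspiration start to the next)."""

    t_insp_start: float
    t_exp_start: float
    t_end: float
    PIP: float
    PEEP: float
    tidal_volume: float = 0.0
    triggered: bool = False

    def __post_init__(self) -> None:
        if not self.t_insp_start < self.t_exp_start < self.t_end:
            raise ConfigurationError(
                f"cycle boundaries must be ordered, got "
                f"{self.t_insp_start}, {self.t_exp_start}, {self.t_end}"
            )

    @property
    def T_i(self) -> float:
        """Inspiratory duration, s."""
        return self.t_exp_start - self.t_insp_start

    @property
    def T_e(self) -> float:
        """Expiratory duration, s."""
        return self.t_end - self.t_exp_start

    @property
    def period(self) -> float:
        return self.t_end - self.t_insp_start

    @property
    def IE_ratio(self) -> float:
        """x in I:E = 1:x, i.e. T_e / T_i."""
        return self.T_e / self.T_i


@dataclass(frozen=True)
class RespiratoryMetrics:
    """Mean +/- sample SD of the per-cycle indices over n_cycles."""

    n_cycles: int
    PIP_mean: float
    PIP_sd: float
    PEEP_mean: float
    PEEP_sd: float
    period_mean: float
    period_sd: float
    RR_mean: float
    RR_sd: float
    IE_mean: float
    IE_sd: float
    tidal_volume_mean: float
    tidal_volume_sd: float

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    # sample SD (n-1 denominator); a single cycle has zero spread by convention
    if len(x) == 1:
        return float(x[0]), 0.0
    return float(np.mean(x)), float(np.std(x, ddof=1))


def segment_breaths(record: WaveformRecord) -> list[BreathCycle]:
    """Segment a waveform record into breath cycles.

    Uses the recorded phase-switch times when present (exact event-located
    boundaries); otherwise falls back to peak/trough detection on the
    pressure trace (see :func:`segment_pressure_trace`).

    Raises :class:`InsufficientDataError` if fewer than two complete
    cycles are found.
    """
    if record.switch_times and len(record.switch_times) > 1:
        return _segment_from_switches(record)
    return segment_pressure_trace(record.t, record.P_alv, Q=record.Q)


def _segment_from_switches(record: WaveformRecord) -> list[BreathCycle]:
    insp_starts = [t for t, ph in record.switch_times if ph is Phase.INSPIRATION]
    exp_starts = [t for t, ph in record.switch_times if ph is Phase.EXPIRATION]

    cycles: list[BreathCycle] = []
    for t0, t1 in zip(insp_starts, insp_starts[1:]):
        mids = [te for te in exp_starts if t0 < te < t1]
        if len(mids) != 1:
            continue  # malformed span; phases should alternate
        te = mids[0]
        sel = (record.t >= t0) & (record.t <= t1)
        p = record.P_alv[sel]
        pip = float(np.max(p))
        # PEEP: pressure at the end-expiratory switch (last sample of the cycle)
        peep = float(p[-1])
        vt = _tidal_volume(record.t[sel], record.Q[sel])
        trig = bool(np.min(record.P_pl[sel]) < -1e-9)
        cycles.append(
            BreathCycle(
                t_insp_start=t0, t_exp_start=te, t_end=t1,
                PIP=pip, PEEP=peep, tidal_volume=vt, triggered=trig,
            )
        )
    if len(cycles) < 2:
        raise InsufficientDataError(
            f"record contains {len(cycles)} complete cycle(s); need at least 2"
        )
    return cycles


def segment_pressure_trace(
    t: np.ndarray,
    pressure: np.ndarray,
    Q: np.ndarray | None = None,
) -> list[BreathCycle]:
    """Segment a bare pressure trace without phase labels.

    Cycle boundaries are troughs (end-expiration) found by threshold-free
    peak detection: local minima separated by at least 0.5 s with
    prominence at least 10% of the trace range.  Within each
    trough-to-trough span, the maximum marks the end of inspiration.
    Tidal volume is integrated from ``Q`` when supplied.
    """
    t = np.asarray(t, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if len(t) != len(pressure) or len(t) < 3:
        raise InsufficientDataError("need matching t/pressure arrays of length >= 3")

    dt_med = float(np.median(np.diff(t)))
    distance = max(1, int(round(_MIN_PEAK_SPACING_S / dt_med)))
    prominence = _PROMINENCE_FRACTION * float(np.ptp(pressure))
    troughs, _ = find_peaks(-pressure, distance=distance, prominence=prominence)

    cycles: list[BreathCycle] = []
    for i0, i1 in zip(troughs, troughs[1:]):
        seg = pressure[i0 : i1 + 1]
        ipk = i0 + int(np.argmax(seg))
        if not (i0 < ipk < i1):
            continue
        vt = 0.0
        if Q is not None:
            vt = _tidal_volume(t[i0 : i1 + 1], np.asarray(Q)[i0 : i1 + 1])
        cycles.append(
            BreathCycle(
                t_insp_start=float(t[i0]),
                t_exp_start=float(t[ipk]),
                t_end=float(t[i1]),
                PIP=float(pressure[ipk]),
                PEEP=float(pressure[i1]),
                tidal_volume=vt,
            )
        )
    if len(cycles) < 2:
        raise InsufficientDataError(
            f"detected {len(cycles)} complete cycle(s); need at least 2"
        )
    return cycles


def _tidal_volume(t: np.ndarray, q: np.ndarray) -> float:
    """Inspired volume: integral of the positive part of flow, L."""
    return float(np.trapezoid(np.clip(q, 0.0, None), t))


def compute_metrics(
    cycles: Sequence[BreathCycle],
    discard: int = 0,
    include_triggered: bool = False,
) -> RespiratoryMetrics:
    """Aggregate per-cycle indices as mean +/- sample SD.

    The first ``discard`` cycles are dropped (start-up transient); cycles
    flagged ``triggered`` are then excluded unless ``include_triggered``.
    Raises :class:`InsufficientDataError` if nothing remains.
    """
    kept = list(cycles)[discard:]
    if not include_triggered:
        kept = [c for c in kept if not c.triggered]
    if not kept:
        raise InsufficientDataError(
            f"no cycles left after discarding {discard} and filtering triggered ones"
        )
    pip, pip_sd = _mean_sd(np.array([c.PIP for c in kept]))
    peep, peep_sd = _mean_sd(np.array([c.PEEP for c in kept]))
    per, per_sd = _mean_sd(np.array([c.period for c in kept]))
    rr, rr_sd = _mean_sd(np.array([60.0 / c.period for c in kept]))
    ie, ie_sd = _mean_sd(np.array([c.IE_ratio for c in kept]))
    vt, vt_sd = _mean_sd(np.array([c.tidal_volume for c in kept]))
    return RespiratoryMetrics(
        n_cycles=len(kept),
        PIP_mean=pip, PIP_sd=pip_sd,
        PEEP_mean=peep, PEEP_sd=peep_sd,
        period_mean=per, period_sd=per_sd,
        RR_mean=rr, RR_sd=rr_sd,
        IE_mean=ie, IE_sd=ie_sd,
        tidal_volume_mean=vt, tidal_volume_sd=vt_sd,
    )


def ec_sweep(
    base: SimulationConfig, d_values: Sequence[float]
) -> pd.DataFrame:
    """Sweep the exhaust-screw occlusion, all else fixed.

    Runs one simulation plus metric extraction per setting and returns a
    table ordered by ``d_EC`` with columns ``d_EC``, ``period_s``,
    ``PIP_cmH2O``, ``PEEP_cmH2O``, ``IE_ratio``, ``n_cycles``.
    """
    rows = []
    for d in sorted(d_values):
        screws = ScrewSettings(d_EC=d, d_FC=base.screws.d_FC, d_SC=base.screws.d_SC)
        cfg = SimulationConfig(
            lung=base.lung, diverter=base.diverter, screws=screws,
            trigger=base.trigger, dt=base.dt, duration=base.duration,
            transient_discard=base.transient_discard,
        )
        rec = simulate(cfg)
        m = compute_metrics(segment_breaths(rec), discard=cfg.transient_discard)
        rows.append(
            {
                "d_EC": d,
                "period_s": m.period_mean,
                "PIP_cmH2O": m.PIP_mean,
                "PEEP_cmH2O": m.PEEP_mean,
                "IE_ratio": m.IE_mean,
                "n_cycles": m.n_cycles,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PeriodDepthFit:
    """OLS fit of oscillation period on exhaust-screw occlusion."""

    slope: float
    intercept: float
    r_squared: float


def fit_period_vs_depth(table: pd.DataFrame) -> PeriodDepthFit:
    """Ordinary least squares of period (s) on EC occlusion fraction.

    ``table`` must have columns ``d_EC`` and ``period_s`` with at least
    three rows.  A positive slope is expected for any valid calibration.
    """
    if len(table) < 3:
        raise InsufficientDataError(
            f"need at least 3 sweep rows for a fit, got {len(table)}"
        )
    res = linregress(table["d_EC"].to_numpy(), table["period_s"].to_numpy())
    return PeriodDepthFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
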