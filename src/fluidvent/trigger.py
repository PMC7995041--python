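"""Patient inspiratory-effort (pleural pressure) model.

A spontaneous inspiratory effort during mechanical ventilation shows up
as a drop in pleural pressure.  Here it is a forced step of magnitude
-A cmH2O with first-order dynamics,

    P_pl(t) = -A * (1 - exp(-(t - t0) / tau)),

initiated at scheduled times t0 and held until the ventilator answers by
switching to inspiration, at which point P_pl resets to zero.  The time
constant defaults to the active lung's tau = R_aw * C.  Efforts whose
scheduled time falls during inspiration are skipped, not queued: the
trigger is only meaningful while the device is in expiration, where the
extra pressure drop pulls alveolar pressure below the low switching
threshold early (a patient-triggered breath).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ConfigurationError
from .lung import LungParameters

__all__ = ["TriggerSchedule", "pleural_pressure", "AMPLITUDE_PROFILES"]

#: Named effort amplitudes, cmH2O: the modeling default and the stronger
#: profile used on bench lung simulators.
AMPLITUDE_PROFILES: dict[str, float] = {"standard": 3.0, "bench": 5.5}


@dataclass(frozen=True)
class TriggerSchedule:
    """Timing, amplitude and time constant of patient efforts.

    Attributes
    ----------
    enabled : bool
    interval_s : float
        Effort initiated every ``interval_s`` seconds (default 4 s, the
        bench protocol of one patient-initiated breath every 4 s).
        Ignored when ``times_s`` is given.
    times_s : sequence of float, optional
        Explicit effort-start times, strictly increasing.
    amplitude : float
        Effort magnitude A >= 0, cmH2O (applied as negative pressure).
    tau_s : float, optional
        First-order time constant, s.  ``None`` means "use the active
        lung's R_aw * C", resolved by the engine at simulation start.
    """

    enabled: bool = False
    interval_s: float = 4.0
    times_s: tuple[float, ...] | None = None
    amplitude: float = 3.0
    tau_s: float | None = None

    def __post_init__(self) -> None:
        if self.times_s is not None:
            object.__setattr__(self, "times_s", tuple(self.times_s))
            ts = self.times_s
            if len(ts) == 0 or any(b <= a for a, b in zip(ts, ts[1:])):
                raise ConfigurationError(
                    "explicit effort times must be non-empty and strictly increasing"
                )
            if ts[0] < 0.0:
                raise ConfigurationError("effort times must be >= 0")
        elif not self.interval_s > 0.0:
            raise ConfigurationError(
                f"trigger interval must be > 0, got {self.interval_s}"
            )
        if not self.amplitude >= 0.0:
            raise ConfigurationError(
                f"trigger amplitude must be >= 0, got {self.amplitude}"
            )
        if self.tau_s is not None and not self.tau_s > 0.0:
            raise ConfigurationError(f"trigger tau must be > 0, got {self.tau_s}")

    def resolve_tau(self, lung: LungParameters) -> "TriggerSchedule":
        """Copy with ``tau_s`` filled in from the lung's R_aw * C if unset."""
        if self.tau_s is not None:
            return self
        tau = lung.tau
        if not tau > 0.0:
            raise ConfigurationError(
                "trigger tau defaults to R_aw * C but the lung has R_aw = 0; "
                "set tau_s explicitly"
            )
        return replace(self, tau_s=tau)

    def effort_times(self, duration: float) -> tuple[float, ...]:
        """Scheduled effort-start times within (0, duration]."""
        if not self.enabled:
            return ()
        if self.times_s is not None:
            return tuple(t for t in self.times_s if t <= duration)
        n = int(duration / self.interval_s)
        return tuple(self.interval_s * k for k in range(1, n + 1))


def pleural_pressure(
    t: float, effort_start: float | None, schedule: TriggerSchedule
) -> float:
    """Pleural pressure (cmH2O) at time ``t`` for an effort begun at
    ``effort_start`` (``None`` when no effort is active).

    Returns 0 with no active effort, otherwise the first-order step
    ``-A * (1 - exp(-(t - effort_start) / tau))``.  ``schedule.tau_s``
    must be resolved (not None).
    """
    if effort_start is None:
        return 0.0
    if t < effort_start:
        raise ConfigurationError(
            f"t={t} precedes the active effort start {effort_start}"
        )
    if schedule.tau_s is None:
        raise ConfigurationError(
            "tau_s unresolved; call TriggerSchedule.resolve_tau first"
        )
    return -schedule.amplitude * (1.0 - math.exp(-(t - effort_start) / schedule.tau_s))
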