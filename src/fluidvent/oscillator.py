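"""Reduced-order model of the bistable fluidic oscillator.

A fluidic oscillator has no moving parts: a jet attaches alternately to
one of two walls (Coanda effect), sending the source flow either into the
lung (inspiration) or past it while the lung empties through the exhaust
channel (expiration).  The jet flips when the downstream (alveolar)
pressure crosses a threshold, high-going at the end of inspiration and
low-going at the end of expiration.  This module abstracts that physics
into three ingredients:

* a **hysteresis switch** -- the diverter is in one of two phases and
  flips at pressure thresholds ``P_high`` (peak inspiratory pressure) and
  ``P_low`` (end-expiratory pressure), with ``P_high > P_low`` so the
  closed loop is a relaxation oscillator;
* **calibration screws** -- three set screws partially occlude the
  exhaust (EC), feedback (FC) and side (SC) channels.  The EC screw sets
  the exhaust flow resistance and hence the expiratory decay rate; the FC
  and SC screws shift the switching thresholds (opening FC or closing SC
  raises PIP);
* the **characteristic fill time** of the vortex chamber,
  ``pi * D^2 * h / (4 * v * mdot)`` -- the design-stage estimate of the
  switching timescale for a chamber of diameter D and height h fed at
  mass flow mdot of fluid with specific volume v.

Default constants are calibrated so that, with the healthy lung preset
and a 30 L/min source, the system oscillates between 8 and 20 cmH2O with
an inspiratory time near 0.9 s and steady periods spanning 3-5 s as the
EC occlusion sweeps [0, 1] (see scripts/calibrate.py; the search is run
once and the constants frozen here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import ConfigurationError

__all__ = [
    "Phase",
    "GeometryParameters",
    "ScrewSettings",
    "DiverterConfig",
    "DiverterState",
    "occlusion_to_resistance",
    "switching_thresholds",
    "lung_flow",
    "next_phase",
    "characteristic_time",
]


class Phase(str, Enum):
    """Diverter phase: source flow to the lung, or lung to the exhaust."""

    INSPIRATION = "INSPIRATION"
    EXPIRATION = "EXPIRATION"

    def other(self) -> "Phase":
        return Phase.EXPIRATION if self is Phase.INSPIRATION else Phase.INSPIRATION


@dataclass(frozen=True)
class GeometryParameters:
    """Vortex-chamber geometry (m).  Defaults: D = 88 mm, h = 2.4 mm."""

    D: float = 0.088
    h: float = 0.0024

    def __post_init__(self) -> None:
        if not (self.D > 0.0 and self.h > 0.0):
            raise ConfigurationError(
                f"chamber diameter and height must be > 0, got D={self.D}, h={self.h}"
            )

    @property
    def volume(self) -> float:
        """Chamber volume pi * D^2 * h / 4, m^3."""
        return math.pi * self.D**2 * self.h / 4.0


@dataclass(frozen=True)
class ScrewSettings:
    """Occlusion fractions of the three calibration screws.

    Each value lies in [0, 1]: 0 = fully open, 1 = fully closed.
    Defaults are the calibrated midpoints.
    """

    d_EC: float = 0.5
    d_FC: float = 0.5
    d_SC: float = 0.5

    def __post_init__(self) -> None:
        for name in ("d_EC", "d_FC", "d_SC"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"screw occlusion {name} must lie in [0, 1], got {v}"
                )


@dataclass(frozen=True)
class DiverterConfig:
    """Constants of the reduced-order diverter.

    Attributes
    ----------
    Q_src : float
        Source volumetric flow, L/s (default 0.5 L/s = 30 L/min).  Zero is
        accepted so that an unpowered system can be simulated and
        diagnosed; oscillation then fails with a clear error.
    R_EC_open, R_EC_span : float
        Exhaust-path resistance law constants, cmH2O*s/L: resistance at
        d_EC = 0 and the additional resistance at full occlusion.
    R_SC_open, R_SC_span : float
        Side-channel leak resistance law constants, cmH2O*s/L.  The side
        channel vents the source flow not delivered to the lung; its
        resistance characterizes that leak path (the inspiratory split
        itself is carried by ``eta_insp``).
    eta_insp : float
        Fraction of the source flow delivered to the lung during
        inspiration, in (0, 1].
    P_high_base, k_SC, k_FC : float
        Upper-threshold map constants, cmH2O.
    P_low_base, m_SC, m_FC : float
        Lower-threshold map constants, cmH2O.

    The threshold maps are affine in the screw occlusions with signs fixed
    by the screws' observed actions (closing SC raises PIP, closing FC
    lowers it); at the midpoint settings they give (20, 8) cmH2O.
    ``P_high > P_low`` is verified for every admissible screw setting at
    construction time.
    """

    Q_src: float = 0.5
    R_EC_open: float = 80.57
    R_EC_span: float = 76.72
    R_SC_open: float = 40.0
    R_SC_span: float = 60.0
    eta_insp: float = 0.69
    P_high_base: float = 20.0
    k_SC: float = 4.0
    k_FC: float = 4.0
    P_low_base: float = 8.0
    m_SC: float = 2.0
    m_FC: float = 2.0

    def __post_init__(self) -> None:
        if not self.Q_src >= 0.0:
            raise ConfigurationError(f"source flow must be >= 0, got {self.Q_src}")
        for name in ("R_EC_open", "R_EC_span", "R_SC_open", "R_SC_span"):
            if not getattr(self, name) > 0.0:
                raise ConfigurationError(
                    f"resistance constant {name} must be > 0, got {getattr(self, name)}"
                )
        if not 0.0 < self.eta_insp <= 1.0:
            raise ConfigurationError(
                f"eta_insp must lie in (0, 1], got {self.eta_insp}"
            )
        # Affine maps attain extremes at corners of the (d_FC, d_SC) square.
        for d_fc in (0.0, 1.0):
            for d_sc in (0.0, 1.0):
                s = ScrewSettings(d_EC=0.0, d_FC=d_fc, d_SC=d_sc)
                switching_thresholds(s, self)


@dataclass
class DiverterState:
    """Current phase and time of the most recent switch."""

    phase: Phase = Phase.INSPIRATION
    t_switch: float = 0.0


def occlusion_to_resistance(d: float, R_open: float, R_span: float) -> float:
    """Flow resistance of a partially occluded channel.

    The screw depth maps linearly onto resistance,

        R(d) = R_open + R_span * d,

    strictly increasing in d and finite at full occlusion.  The linear law
    reflects the observed proportionality between exhaust-screw depth and
    oscillation period over the full adjustment range.

    Parameters
    ----------
    d : float
        Occlusion fraction in [0, 1].
    R_open, R_span : float
        Resistance at d = 0 and span to d = 1, cmH2O*s/L; both > 0.
    """
    if not 0.0 <= d <= 1.0:
        raise ConfigurationError(f"occlusion fraction must lie in [0, 1], got {d}")
    if not (R_open > 0.0 and R_span > 0.0):
        raise ConfigurationError(
            f"resistances must be > 0, got R_open={R_open}, R_span={R_span}"
        )
    return R_open + R_span * d


def switching_thresholds(
    settings: ScrewSettings, config: DiverterConfig
) -> tuple[float, float]:
    """Pressure thresholds (P_high, P_low) in cmH2O for the given screws.

    P_high = P_high_base + k_SC * d_SC - k_FC * d_FC
    P_low  = P_low_base  + m_SC * d_SC - m_FC * d_FC

    Closing the SC screw raises PIP; closing the FC screw lowers it.
    Raises :class:`ConfigurationError` if the map yields
    ``P_high <= P_low`` (no oscillation possible).
    """
    p_high = config.P_high_base + config.k_SC * settings.d_SC - config.k_FC * settings.d_FC
    p_low = config.P_low_base + config.m_SC * settings.d_SC - config.m_FC * settings.d_FC
    if not p_high > p_low:
        raise ConfigurationError(
            f"threshold map gives P_high={p_high} <= P_low={p_low} "
            f"at d_FC={settings.d_FC}, d_SC={settings.d_SC}: no oscillation possible"
        )
    return p_high, p_low


def lung_flow(
    phase: Phase,
    P: float,
    settings: ScrewSettings,
    config: DiverterConfig,
    R_exp: float | None = None,
) -> float:
    """Lung flow (L/s, positive into the lung) for the given phase.

    During INSPIRATION the diverter delivers a constant fraction of the
    source flow, ``Q = eta_insp * Q_src``, independent of pressure (the
    remainder vents through the side channel).  During EXPIRATION the lung
    discharges through the exhaust path, ``Q = -P / R_exp``, where ``P``
    is the driving pressure referenced to atmosphere and ``R_exp`` is the
    total expiratory resistance.  When ``R_exp`` is not supplied it
    defaults to the EC channel resistance alone; the engine assembles the
    full path by adding the airway resistance.
    """
    if phase is Phase.INSPIRATION:
        return config.eta_insp * config.Q_src
    if R_exp is None:
        R_exp = occlusion_to_resistance(settings.d_EC, config.R_EC_open, config.R_EC_span)
    return -P / R_exp


def next_phase(phase: Phase, P_alv: float, P_high: float, P_low: float) -> Phase:
    """Hysteretic switching rule.

    INSPIRATION -> EXPIRATION when P_alv >= P_high; EXPIRATION ->
    INSPIRATION when P_alv <= P_low; otherwise the phase is unchanged.
    Inside the hysteresis band the rule is idempotent.
    """
    if not P_high > P_low:
        raise ConfigurationError(
            f"hysteresis requires P_high > P_low, got {P_high} <= {P_low}"
        )
    if phase is Phase.INSPIRATION and P_alv >= P_high:
        return Phase.EXPIRATION
    if phase is Phase.EXPIRATION and P_alv <= P_low:
        return Phase.INSPIRATION
    return phase


def characteristic_time(
    geom: GeometryParameters,
    v: float | None = None,
    mdot: float | None = None,
    *,
    volumetric_flow: float | None = None,
) -> float:
    """Vortex-chamber fill time, the oscillator's design timescale (s).

        dt_c = pi * D^2 * h / (4 * v * mdot)

    with v the specific volume (m^3/kg) and mdot the mass flow (kg/s).
    Since ``v * mdot`` is the volumetric flow, the calculation may instead
    be given ``volumetric_flow`` (m^3/s) directly.
    """
    if volumetric_flow is None:
        if v is None or mdot is None:
            raise ConfigurationError(
                "provide either (v, mdot) or volumetric_flow"
            )
        if not (v > 0.0 and mdot > 0.0):
            raise ConfigurationError(
                f"specific volume and mass flow must be > 0, got v={v}, mdot={mdot}"
            )
        volumetric_flow = v * mdot
    if not volumetric_flow > 0.0:
        raise ConfigurationError(
            f"volumetric flow must be > 0, got {volumetric_flow}"
        )
    return geom.volume / volumetric_flow
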