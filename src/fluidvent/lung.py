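"""Single-compartment Windkessel lung model.

The lung is a resistance R_aw in series with a compliance C.  Alveolar
pressure obeys the first-order equation of motion of the respiratory
system,

    P_alv(t) = Q(t) * R_aw + V(t) / C + P_peep + P_pl(t),

where Q is flow into the lung (L/s), V = integral of Q is the volume
above the end-expiratory baseline (L), P_peep is the baseline
end-expiratory pressure, and P_pl is the pleural (respiratory-muscle)
pressure contributed by patient effort.  All pressures are gauge
(atmosphere = 0) in cmH2O.

Three named presets cover the compliance range used to emulate lung
pathology on bench respiratory simulators: fibrosis (stiff, 10 mL/cmH2O),
healthy (30 mL/cmH2O) and emphysema (compliant, 50 mL/cmH2O), all with
airway resistance 3 cmH2O/L/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .errors import ConfigurationError
from .units import ml_per_cmh2o_to_l

__all__ = [
    "LungParameters",
    "LungState",
    "alveolar_pressure",
    "lung_preset",
    "LUNG_PRESETS",
]

#: Compliance below which the single-compartment model is dubious
#: (mL/cmH2O); accepted with a warning, not rejected.
_LOW_COMPLIANCE_WARN_ML = 5.0


@dataclass(frozen=True)
class LungParameters:
    """Windkessel lung parameters (internal units).

    Attributes
    ----------
    R_aw : float
        Airway resistance, cmH2O*s/L.  Must be >= 0.
    C : float
        Lung compliance, L/cmH2O.  Must be > 0.
    P_peep_base : float
        Baseline end-expiratory pressure, cmH2O.  Must be >= 0.
    label : str
        Free-text condition name.
    """

    R_aw: float = 3.0
    C: float = 0.030
    P_peep_base: float = 8.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.R_aw >= 0.0:
            raise ConfigurationError(f"airway resistance must be >= 0, got {self.R_aw}")
        if not self.C > 0.0:
            raise ConfigurationError(f"lung compliance must be > 0, got {self.C}")
        if not self.P_peep_base >= 0.0:
            raise ConfigurationError(
                f"baseline PEEP must be >= 0, got {self.P_peep_base}"
            )
        if self.C < ml_per_cmh2o_to_l(_LOW_COMPLIANCE_WARN_ML):
            warnings.warn(
                f"compliance {self.C * 1000:.1f} mL/cmH2O is below "
                f"{_LOW_COMPLIANCE_WARN_ML} mL/cmH2O; the lumped model is "
                "accepted but may be unrealistically stiff",
                stacklevel=3,
            )

    @property
    def tau(self) -> float:
        """Intrinsic RC time constant R_aw * C, s."""
        return self.R_aw * self.C


@dataclass
class LungState:
    """Instantaneous lung state (internal units).

    ``P_alv`` always equals the Windkessel expression of the other fields.
    """

    t: float = 0.0
    V: float = 0.0
    Q: float = 0.0
    P_alv: float = 0.0
    P_pl: float = 0.0


def alveolar_pressure(
    params: LungParameters, Q: float, V: float, P_pl: float = 0.0
) -> float:
    """Alveolar pressure from the Windkessel equation of motion.

    Parameters
    ----------
    params : LungParameters
    Q : float
        Flow into the lung, L/s (negative during expiration).
    V : float
        Volume above the end-expiratory baseline, L.
    P_pl : float
        Pleural (effort) pressure, cmH2O.

    Returns
    -------
    float
        ``Q * R_aw + V / C + P_peep_base + P_pl`` in cmH2O.
    """
    return Q * params.R_aw + V / params.C + params.P_peep_base + P_pl


#: Preset compliances in mL/cmH2O keyed by condition name.
LUNG_PRESETS: dict[str, float] = {
    "fibrosis": 10.0,
    "healthy": 30.0,
    "emphysema": 50.0,
}


def lung_preset(condition: str) -> LungParameters:
    """Return the named lung-condition preset.

    ``condition`` must be one of ``fibrosis``, ``healthy`` or ``emphysema``
    (R_aw = 3 cmH2O*s/L; C = 10, 30 or 50 mL/cmH2O respectively).
    """
    try:
        c_ml = LUNG_PRESETS[condition]
    except KeyError:
        valid = ", ".join(sorted(LUNG_PRESETS))
        raise ConfigurationError(
            f"unknown lung preset {condition!r}; valid names: {valid}"
        ) from None
    return LungParameters(R_aw=3.0, C=ml_per_cmh2o_to_l(c_ml), label=condition)


def with_compliance_ml(params: LungParameters, c_ml: float) -> LungParameters:
    """Copy of ``params`` with compliance given in mL/cmH2O."""
    return replace(params, C=ml_per_cmh2o_to_l(c_ml))
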