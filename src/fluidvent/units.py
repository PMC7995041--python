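"""Unit conversions.

Internal units are fixed throughout the package: pressures in cmH2O,
volumes in L, flows in L/s, times in s, lengths in m.  User-facing inputs
(configs, CLI flags) accept the conventions common on ventilator spec
sheets -- compliance in mL/cmH2O, flow in L/min, lengths in mm -- and are
converted on ingest by these helpers.  All conversions are exact scalings,
so round-tripping is lossless to machine precision.
"""


def lpm_to_lps(q_lpm: float) -> float:
    """L/min -> L/s."""
    return q_lpm / 60.0


def lps_to_lpm(q_lps: float) -> float:
    """L/s -> L/min."""
    return q_lps * 60.0


def ml_per_cmh2o_to_l(c_ml: float) -> float:
    """Compliance mL/cmH2O -> L/cmH2O."""
    return c_ml / 1000.0


def l_to_ml_per_cmh2o(c_l: float) -> float:
    """Compliance L/cmH2O -> mL/cmH2O."""
    return c_l * 1000.0


def mm_to_m(x_mm: float) -> float:
    """mm -> m."""
    return x_mm / 1000.0


def m_to_mm(x_m: float) -> float:
    """m -> mm."""
    return x_m * 1000.0
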