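"""Configuration and waveform I/O.

Config files are YAML (or JSON) with named blocks ``lung``, ``diverter``,
``screws``, ``trigger`` and ``sim``; every block and every key is
optional and defaults apply.  User-facing values are in human units --
compliance in mL/cmH2O, flows in L/min -- and are converted to internal
units (L/cmH2O, L/s) on load; see docs/config_schema.md for the full
schema.  Waveforms are exported as plain CSV with one header row and
fixed column names (t_s, P_alv_cmH2O, P_pl_cmH2O, Q_Lps, V_L, phase);
times are printed to 6 decimals and all other numeric columns to 4, and
re-importing reproduces the arrays to that printed precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SimulationConfig, WaveformRecord
from .errors import ConfigurationError
from .lung import LungParameters, lung_preset
from .oscillator import DiverterConfig, Phase, ScrewSettings
from .trigger import AMPLITUDE_PROFILES, TriggerSchedule
from .units import (
    l_to_ml_per_cmh2o,
    lpm_to_lps,
    lps_to_lpm,
    ml_per_cmh2o_to_l,
)

__all__ = [
    "load_config",
    "save_config",
    "config_to_dict",
    "waveform_to_csv",
    "waveform_from_csv",
    "plot_waveform",
]

WAVEFORM_COLUMNS = ["t_s", "P_alv_cmH2O", "P_pl_cmH2O", "Q_Lps", "V_L", "phase"]


# ---------------------------------------------------------------- config

def _lung_from_dict(d: dict) -> LungParameters:
    if "preset" in d:
        params = lung_preset(d["preset"])
        extra = {k: v for k, v in d.items() if k != "preset"}
    else:
        params = LungParameters()
        extra = dict(d)
    kw = {
        "R_aw": params.R_aw,
        "C": params.C,
        "P_peep_base": params.P_peep_base,
        "label": params.label,
    }
    mapping = {
        "resistance_cmh2o_per_lps": ("R_aw", float),
        "compliance_ml_per_cmh2o": ("C", ml_per_cmh2o_to_l),
        "peep_base_cmh2o": ("P_peep_base", float),
        "label": ("label", str),
    }
    for key, value in extra.items():
        if key not in mapping:
            raise ConfigurationError(f"unknown lung config key {key!r}")
        name, conv = mapping[key]
        kw[name] = conv(value)
    return LungParameters(**kw)


def _diverter_from_dict(d: dict) -> DiverterConfig:
    kw = {}
    mapping = {
        "source_flow_lpm": ("Q_src", lpm_to_lps),
        "r_ec_open": ("R_EC_open", float),
        "r_ec_span": ("R_EC_span", float),
        "r_sc_open": ("R_SC_open", float),
        "r_sc_span": ("R_SC_span", float),
        "eta_insp": ("eta_insp", float),
        "p_high_base": ("P_high_base", float),
        "k_sc": ("k_SC", float),
        "k_fc": ("k_FC", float),
        "p_low_base": ("P_low_base", float),
        "m_sc": ("m_SC", float),
        "m_fc": ("m_FC", float),
    }
    for key, value in d.items():
        if key not in mapping:
            raise ConfigurationError(f"unknown diverter config key {key!r}")
        name, conv = mapping[key]
        kw[name] = conv(value)
    return DiverterConfig(**kw)


def _screws_from_dict(d: dict) -> ScrewSettings:
    kw = {}
    for key, value in d.items():
        if key not in ("ec", "fc", "sc"):
            raise ConfigurationError(f"unknown screws config key {key!r}")
        kw[f"d_{key.upper()}"] = float(value)
    return ScrewSettings(**kw)


def _trigger_from_dict(d: dict) -> TriggerSchedule:
    kw = {}
    mapping = {
        "enabled": ("enabled", bool),
        "interval_s": ("interval_s", float),
        "times_s": ("times_s", lambda v: tuple(float(x) for x in v)),
        "amplitude_cmh2o": ("amplitude", float),
        "tau_s": ("tau_s", float),
    }
    for key, value in d.items():
        if key == "amplitude_profile":
            try:
                kw["amplitude"] = AMPLITUDE_PROFILES[value]
            except KeyError:
                valid = ", ".join(sorted(AMPLITUDE_PROFILES))
                raise ConfigurationError(
                    f"unknown amplitude profile {value!r}; valid: {valid}"
                ) from None
            continue
        if key not in mapping:
            raise ConfigurationError(f"unknown trigger config key {key!r}")
        name, conv = mapping[key]
        kw[name] = conv(value)
    return TriggerSchedule(**kw)


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a nested config dict."""
    known = {"lung", "diverter", "screws", "trigger", "sim"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config block(s): {sorted(unknown)}")
    sim = dict(data.get("sim", {}))
    kw = {}
    for key, name in (("dt_s", "dt"), ("duration_s", "duration"),
                      ("transient_discard", "transient_discard")):
        if key in sim:
            kw[name] = type(SimulationConfig.__dataclass_fields__[name].default)(
                sim.pop(key)
            )
    if sim:
        raise ConfigurationError(f"unknown sim config key(s): {sorted(sim)}")
    return SimulationConfig(
        lung=_lung_from_dict(data.get("lung", {})),
        diverter=_diverter_from_dict(data.get("diverter", {})),
        screws=_screws_from_dict(data.get("screws", {})),
        trigger=_trigger_from_dict(data.get("trigger", {})),
        **kw,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """Serialize a config back to the human-unit dict form."""
    lung = {
        "resistance_cmh2o_per_lps": config.lung.R_aw,
        "compliance_ml_per_cmh2o": l_to_ml_per_cmh2o(config.lung.C),
        "peep_base_cmh2o": config.lung.P_peep_base,
        "label": config.lung.label,
    }
    d = config.diverter
    diverter = {
        "source_flow_lpm": lps_to_lpm(d.Q_src),
        "r_ec_open": d.R_EC_open,
        "r_ec_span": d.R_EC_span,
        "r_sc_open": d.R_SC_open,
        "r_sc_span": d.R_SC_span,
        "eta_insp": d.eta_insp,
        "p_high_base": d.P_high_base,
        "k_sc": d.k_SC,
        "k_fc": d.k_FC,
        "p_low_base": d.P_low_base,
        "m_sc": d.m_SC,
        "m_fc": d.m_FC,
    }
    screws = {
        "ec": config.screws.d_EC,
        "fc": config.screws.d_FC,
        "sc": config.screws.d_SC,
    }
    t = config.trigger
    trigger: dict = {"enabled": t.enabled, "amplitude_cmh2o": t.amplitude}
    if t.times_s is not None:
        trigger["times_s"] = list(t.times_s)
    else:
        trigger["interval_s"] = t.interval_s
    if t.tau_s is not None:
        trigger["tau_s"] = t.tau_s
    return {
        "lung": lung,
        "diverter": diverter,
        "screws": screws,
        "trigger": trigger,
        "sim": {
            "dt_s": config.dt,
            "duration_s": config.duration,
            "transient_discard": config.transient_discard,
        },
    }


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML or JSON config file (extension decides the parser)."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigurationError(f"cannot read config file {path}: {exc}") from exc
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"malformed config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data)}")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as YAML (or JSON for a ``.json`` path)."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# -------------------------------------------------------------- waveform

def waveform_to_csv(record: WaveformRecord, path: str | Path) -> None:
    """Export a waveform record as CSV (times to 6 dp, signals to 4 dp)."""
    df = pd.DataFrame(
        {
            "t_s": record.t,
            "P_alv_cmH2O": record.P_alv,
            "P_pl_cmH2O": record.P_pl,
            "Q_Lps": record.Q,
            "V_L": record.V,
            "phase": record.phase,
        }
    )
    df["t_s"] = df["t_s"].map(lambda x: f"{x:.6f}")
    for col in ("P_alv_cmH2O", "P_pl_cmH2O", "Q_Lps", "V_L"):
        df[col] = df[col].map(lambda x: f"{x:.4f}")
    df.to_csv(path, index=False)


def waveform_from_csv(path: str | Path) -> WaveformRecord:
    """Re-import a waveform CSV written by :func:`waveform_to_csv`.

    Accepts the full column set or a minimal two-column (time, pressure)
    file.  Switch times are reconstructed from the phase column: the
    convention is that the sample *at* a switch instant carries the
    pre-switch phase, so a switch time is the time of the last sample of
    the outgoing phase.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise ConfigurationError(f"cannot read waveform CSV {path}: {exc}") from exc

    if list(df.columns[:2]) != WAVEFORM_COLUMNS[:2] and len(df.columns) == 2:
        df.columns = ["t_s", "P_alv_cmH2O"]
    if "t_s" not in df.columns or "P_alv_cmH2O" not in df.columns:
        raise ConfigurationError(
            f"waveform CSV {path} must contain at least t_s and P_alv_cmH2O "
            f"(got columns {list(df.columns)})"
        )
    n = len(df)
    t = df["t_s"].to_numpy(dtype=float)

    def col(name: str) -> np.ndarray:
        if name in df.columns:
            return df[name].to_numpy(dtype=float)
        return np.zeros(n)

    if "phase" in df.columns:
        phase = df["phase"].to_numpy(dtype=str)
        switch_times: list[tuple[float, Phase]] = [(float(t[0]), Phase(phase[0]))]
        for i in range(1, n):
            if phase[i] != phase[i - 1]:
                # sample i-1 is the last of the outgoing phase = the switch instant
                switch_times.append((float(t[i - 1]), Phase(phase[i])))
    else:
        phase = np.array([""] * n)
        switch_times = []

    return WaveformRecord(
        t=t,
        P_alv=df["P_alv_cmH2O"].to_numpy(dtype=float),
        P_pl=col("P_pl_cmH2O"),
        Q=col("Q_Lps"),
        V=col("V_L"),
        phase=phase,
        switch_times=switch_times,
    )


def plot_waveform(record: WaveformRecord, path: str | Path) -> None:
    """Save a basic two-panel (pressure, flow) waveform figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_p, ax_q) = plt.subplots(2, 1, sharex=True, figsize=(9, 5))
    ax_p.plot(record.t, record.P_alv, lw=0.8, label="P_alv")
    if np.any(record.P_pl != 0.0):
        ax_p.plot(record.t, record.P_pl, lw=0.8, label="P_pl")
        ax_p.legend(loc="upper right", fontsize=8)
    ax_p.set_ylabel("pressure (cmH2O)")
    ax_q.plot(record.t, record.Q, lw=0.8, color="tab:orange")
    ax_q.set_ylabel("flow (L/s)")
    ax_q.set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
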