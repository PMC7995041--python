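"""Synthetic respiratory-waveform generator.

Produces ventilator-like pressure waveforms with *known* PIP, PEEP,
inspiratory/expiratory durations and noise level, for testing the
analytics independently of the simulator.  Each cycle is piecewise
exponential: a rise from PEEP whose asymptote is chosen so the pressure
reaches PIP at exactly T_i, then a decay whose asymptote is chosen so it
returns to PEEP at exactly T_e.  Optional additive white Gaussian noise
is drawn from a seeded generator, so fixtures are reproducible.

A companion flow trace is derived from the noise-free pressure through a
nominal compliance (Q = C_nom * dP/dt), which keeps the record's
flow/volume consistency exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .engine import WaveformRecord
from .oscillator import Phase

__all__ = ["FixtureSpec", "make_synthetic_waveform"]

#: Nominal compliance (L/cmH2O) used to derive the companion flow trace.
_C_NOMINAL = 0.030


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic waveform.

    Pressures in cmH2O, times in s.  ``rise_tau``/``decay_tau`` shape the
    exponential segments; ``noise_sd`` is the SD of additive Gaussian
    noise on the pressure trace, drawn with ``seed``.
    """

    PIP: float = 17.0
    PEEP: float = 11.0
    T_i: float = 1.0
    T_e: float = 3.0
    n_cycles: int = 10
    rise_tau: float = 0.3
    decay_tau: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not self.PIP > self.PEEP:
            raise ConfigurationError(
                f"PIP must exceed PEEP, got {self.PIP} <= {self.PEEP}"
            )
        if not (self.T_i > 0.0 and self.T_e > 0.0):
            raise ConfigurationError("T_i and T_e must be > 0")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if self.noise_sd < 0.0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (self.rise_tau > 0.0 and self.decay_tau > 0.0):
            raise ConfigurationError("rise_tau and decay_tau must be > 0")
        if not self.dt > 0.0:
            raise ConfigurationError("dt must be > 0")


def make_synthetic_waveform(spec: FixtureSpec) -> WaveformRecord:
    """Build the synthetic record described by ``spec``.

    Sample times include the exact cycle and phase boundaries, so with
    zero noise the trace attains PIP and PEEP exactly and the recovered
    period equals ``T_i + T_e`` to machine precision.
    """
    period = spec.T_i + spec.T_e
    # asymptotes chosen so the segments hit PIP at T_i and PEEP at T_e exactly
    p_rise_inf = spec.PEEP + (spec.PIP - spec.PEEP) / (
        1.0 - math.exp(-spec.T_i / spec.rise_tau)
    )
    e_dec = math.exp(-spec.T_e / spec.decay_tau)
    p_dec_inf = (spec.PEEP - spec.PIP * e_dec) / (1.0 - e_dec)

    # per-phase local time grids, boundaries exact
    s_i = np.arange(0.0, spec.T_i, spec.dt)
    s_e = np.arange(0.0, spec.T_e, spec.dt)

    p_i = p_rise_inf + (spec.PEEP - p_rise_inf) * np.exp(-s_i / spec.rise_tau)
    p_e = p_dec_inf + (spec.PIP - p_dec_inf) * np.exp(-s_e / spec.decay_tau)
    # analytic dP/dt for the companion flow trace
    dp_i = -(spec.PEEP - p_rise_inf) / spec.rise_tau * np.exp(-s_i / spec.rise_tau)
    dp_e = -(spec.PIP - p_dec_inf) / spec.decay_tau * np.exp(-s_e / spec.decay_tau)

    ts, ps, qs, phs = [], [], [], []
    switch_times: list[tuple[float, Phase]] = []
    insp, exp = Phase.INSPIRATION.value, Phase.EXPIRATION.value
    for k in range(spec.n_cycles):
        t0 = k * period
        switch_times.append((t0, Phase.INSPIRATION))
        ts.append(t0 + s_i)
        ps.append(p_i)
        qs.append(_C_NOMINAL * dp_i)
        # engine convention: the sample at a switch instant carries the
        # outgoing phase, so the boundary sample of each segment keeps the
        # previous label (except at t = 0, where the record begins)
        first = insp if k == 0 else exp
        phs.append([first] + [insp] * (len(s_i) - 1))
        switch_times.append((t0 + spec.T_i, Phase.EXPIRATION))
        ts.append(t0 + spec.T_i + s_e)
        ps.append(p_e)
        qs.append(_C_NOMINAL * dp_e)
        phs.append([insp] + [exp] * (len(s_e) - 1))
    # closing sample at the final end-expiration point
    t_end = spec.n_cycles * period
    switch_times.append((t_end, Phase.INSPIRATION))
    ts.append(np.array([t_end]))
    ps.append(np.array([spec.PEEP]))
    qs.append(np.array([_C_NOMINAL * dp_e[-1] if len(dp_e) else 0.0]))
    phs.append([Phase.EXPIRATION.value])

    t = np.concatenate(ts)
    p_clean = np.concatenate(ps)
    q = np.concatenate(qs)
    phase = np.array([x for chunk in phs for x in chunk])
    v = _C_NOMINAL * (p_clean - spec.PEEP)

    p = p_clean
    if spec.noise_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        p = p_clean + rng.normal(0.0, spec.noise_sd, size=len(p_clean))

    return WaveformRecord(
        t=t,
        P_alv=p,
        P_pl=np.zeros_like(t),
        Q=q,
        V=v,
        phase=phase,
        switch_times=switch_times,
    )
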