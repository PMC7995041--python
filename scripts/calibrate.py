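"""One-off calibration of the diverter constants.

Not part of the runtime path.  Solves for the three free constants of the
reduced-order diverter so that, with the healthy lung preset and a
30 L/min source:

* the steady inspiratory time is ~0.9 s (eta_insp) -- the unique window
  in which both I:E endpoints (~1:2 at the fastest setting, ~1:5 at the
  slowest) are attainable given the near-constant inspiratory time of
  constant-flow charging;
* the mean steady period is 3.000 s at d_EC = 0 (R_EC_open) and 5.000 s
  at d_EC = 1 (R_EC_span), bracketing the tunable respiratory-rate range
  of 12-20 breaths/min.

The solved constants are frozen as the DiverterConfig defaults; run this
script to reproduce or re-derive them:

    python scripts/calibrate.py
"""

from __future__ import annotations

import dataclasses

from fluidvent import (
    DiverterConfig,
    ScrewSettings,
    SimulationConfig,
    compute_metrics,
    lung_preset,
    segment_breaths,
    simulate,
)

T_FAST = 3.0   # target mean period at d_EC = 0, s
T_SLOW = 5.0   # target mean period at d_EC = 1, s
ETA = 0.69     # delivered inspiratory fraction (sets T_i ~ 0.93 s)


def mean_period(r_open: float, r_span: float, d_ec: float) -> tuple[float, float]:
    div = dataclasses.replace(
        DiverterConfig(), eta_insp=ETA, R_EC_open=r_open, R_EC_span=max(r_span, 1e-6)
    )
    cfg = SimulationConfig(
        lung=lung_preset("healthy"),
        diverter=div,
        screws=ScrewSettings(d_EC=d_ec),
        duration=40.0,
    )
    m = compute_metrics(segment_breaths(simulate(cfg)), discard=2)
    t_i = m.period_mean / (1.0 + m.IE_mean)
    return m.period_mean, t_i


def bisect(f, lo: float, hi: float, tol: float = 1e-3) -> float:
    flo, fhi = f(lo), f(hi)
    assert flo * fhi < 0, (lo, hi, flo, fhi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) * flo <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def main() -> None:
    r_open = bisect(lambda r: mean_period(r, 50.0, 0.0)[0] - T_FAST, 40.0, 150.0)
    r_span = bisect(
        lambda s: mean_period(r_open, s, 1.0)[0] - T_SLOW, 10.0, 200.0
    )
    print(f"eta_insp  = {ETA}")
    print(f"R_EC_open = {r_open:.2f}")
    print(f"R_EC_span = {r_span:.2f}")
    for d in (0.0, 0.5, 1.0):
        period, t_i = mean_period(r_open, r_span, d)
        print(
            f"d_EC={d:3.1f}: period={period:.4f} s  T_i={t_i:.4f} s  "
            f"I:E=1:{(period - t_i) / t_i:.3f}"
        )


if __name__ == "__main__":
    main()
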