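# fluidvent

A lumped-parameter simulator of an educational mechanical ventilator
driven by a bistable **fluidic oscillator** — a no-moving-parts flow
chamber that converts a constant 30 L/min air supply into alternating
inspiratory and expiratory flow — coupled to a single-compartment
**Windkessel lung**.  It is intended for people studying or teaching
respiratory biomechanics who want to explore how PIP, PEEP, respiratory
rate, I:E ratio and patient triggering emerge from a handful of physical
parameters, without running 3-D CFD.

## Model in brief

The lung is a resistance–compliance pair obeying the equation of motion
of the respiratory system,

    P_alv(t) = Q·R_aw + (1/C)∫Q dt + P_peep + P_pl ,

and the oscillator is a two-state hysteresis switch: inspiration
delivers a constant fraction of the source flow until P_alv reaches
P_high (PIP, 20 cmH2O at default calibration), then the lung discharges
through the exhaust channel — an RC decay with time constant
(R_EC + R_aw)·C — until P_alv falls to P_low (PEEP, 8 cmH2O) and the
cycle repeats.  Three calibration screws are modeled: the EC screw sets
the exhaust resistance (and thereby the period, linearly), while the FC
and SC screws shift the switching thresholds (closing SC raises PIP,
closing FC lowers it).  Patient effort is a first-order pleural-pressure
step of −3 cmH2O with τ = R_aw·C that, during expiration, pulls the
pressure below P_low early — a patient-triggered breath.  Full details
and assumptions: [docs/methods.md](docs/methods.md).

## Worked example

Simulate the default healthy lung (C = 30 mL/cmH2O, R = 3 cmH2O/L/s,
screws at midpoints) for 60 s and extract per-cycle metrics:

```
$ fluidvent simulate --config examples/config_healthy.yaml --waveform-out wave.csv
{
  "n_cycles": 12,
  "PIP_mean": 20.00007343128611,
  "PEEP_mean": 7.999993061299121,
  "period_mean": 4.002158854163258,
  "RR_mean": 14.99190866390414,
  "IE_mean": 3.2760962715637123,
  "tidal_volume_mean": 0.3228984374997254,
  ...
}
```

The waveform oscillates between a PEEP of 8.0 and a PIP of 20.0 cmH2O
with a 4.0 s period (15 breaths/min), I:E ≈ 1:3.3, moving ≈ 0.32 L per
breath; 12 steady cycles remain after the two start-up cycles are
discarded.  Sweeping the exhaust-screw occlusion from 0 to 1
(`fluidvent sweep`) moves the period linearly from 3.0 s to 5.0 s
(RR 20 → 12 breaths/min) while PIP and PEEP stay put.  The design-stage
fill time of the 88 mm × 2.4 mm vortex chamber at 30 L/min:

```
$ fluidvent design-time --diameter-mm 88 --height-mm 2.4 --flow-lpm 30
0.0291942
```

Other subcommands: `analyze` (metrics from a waveform CSV), `presets`
(the fibrosis/healthy/emphysema lung presets), `fixture` (synthetic
waveforms with known PIP/PEEP/period for testing analytics).  The
config schema is documented in [docs/config_schema.md](docs/config_schema.md).

The same surface is available as a library:

```python
from fluidvent import SimulationConfig, lung_preset, simulate, segment_breaths, compute_metrics

cfg = SimulationConfig(lung=lung_preset("healthy"))
metrics = compute_metrics(segment_breaths(simulate(cfg)), discard=2)
print(metrics.PIP_mean, metrics.PEEP_mean, metrics.RR_mean)
```

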