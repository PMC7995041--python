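# Configuration file schema

Configs are YAML (or JSON, chosen by file extension) with up to five
blocks.  Every block and every key is optional; omitted values take the
calibrated defaults shown below.  All user-facing values are in the
human units common on ventilator spec sheets; they are converted to
internal units (cmH2O, L, s) on load.  Unknown blocks or keys are
rejected with a diagnostic.

## `lung` — Windkessel lung

| key | unit | default | meaning |
| --- | --- | --- | --- |
| `preset` | — | — | one of `fibrosis`, `healthy`, `emphysema`; sets R and C, remaining keys override |
| `resistance_cmh2o_per_lps` | cmH2O·s/L | 3.0 | airway resistance R_aw (>= 0) |
| `compliance_ml_per_cmh2o` | mL/cmH2O | 30.0 | compliance C (> 0; values below 5 warn) |
| `peep_base_cmh2o` | cmH2O | 8.0 | baseline end-expiratory pressure |
| `label` | — | `""` | free-text condition name |

## `diverter` — reduced-order oscillator constants

| key | unit | default | meaning |
| --- | --- | --- | --- |
| `source_flow_lpm` | L/min | 30.0 | constant source flow Q_src (>= 0) |
| `eta_insp` | — | 0.69 | fraction of source flow delivered to the lung during inspiration, (0, 1] |
| `r_ec_open` | cmH2O·s/L | 80.57 | exhaust-channel resistance at zero occlusion |
| `r_ec_span` | cmH2O·s/L | 76.72 | extra exhaust resistance at full occlusion |
| `r_sc_open` | cmH2O·s/L | 40.0 | side-channel leak resistance at zero occlusion |
| `r_sc_span` | cmH2O·s/L | 60.0 | extra side-channel resistance at full occlusion |
| `p_high_base`, `k_sc`, `k_fc` | cmH2O | 20, 4, 4 | upper-threshold map: P_high = p_high_base + k_sc·d_SC − k_fc·d_FC |
| `p_low_base`, `m_sc`, `m_fc` | cmH2O | 8, 2, 2 | lower-threshold map: P_low = p_low_base + m_sc·d_SC − m_fc·d_FC |

The threshold maps must satisfy P_high > P_low for every admissible
screw setting; this is verified when the block is loaded.

## `screws` — calibration screw occlusions

| key | default | meaning |
| --- | --- | --- |
| `ec` | 0.5 | exhaust-channel occlusion in [0, 1] (tunes the period) |
| `fc` | 0.5 | feedback-channel occlusion (closing lowers PIP) |
| `sc` | 0.5 | side-channel occlusion (closing raises PIP) |

## `trigger` — patient inspiratory effort

| key | unit | default | meaning |
| --- | --- | --- | --- |
| `enabled` | — | false | |
| `interval_s` | s | 4.0 | one effort every `interval_s` (ignored if `times_s` given) |
| `times_s` | s | — | explicit strictly increasing effort-start times |
| `amplitude_cmh2o` | cmH2O | 3.0 | effort magnitude A (applied as −A) |
| `amplitude_profile` | — | — | named amplitude: `standard` (3.0) or `bench` (5.5) |
| `tau_s` | s | R_aw·C | first-order time constant (defaults to the active lung's RC) |

## `sim` — integration controls

| key | unit | default | meaning |
| --- | --- | --- | --- |
| `dt_s` | s | 0.001 | base integration step |
| `duration_s` | s | 60.0 | simulated horizon (>= 10·dt) |
| `transient_discard` | — | 2 | start-up cycles dropped by downstream statistics |

A complete example is in `examples/config_healthy.yaml`.
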