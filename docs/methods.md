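# Methods

## The system being modeled

A bistable fluidic oscillator is a planar flow chamber with no moving
parts.  A jet entering the nozzle–diverter region attaches to one of two
walls (the Coanda effect) and therefore feeds either the patient outlet
(inspiration) or lets the lung empty through the exhaust channel
(expiration).  The jet flips when the pressure downstream — the lung —
crosses a threshold: high-going at end-inspiration, low-going at
end-expiration.  Driven by a constant air supply, the device therefore
ventilates a passive lung with a self-excited pressure oscillation whose
peak (PIP), floor (PEEP) and period are tuned by three set screws that
partially occlude the exhaust (EC), feedback (FC) and side (SC)
channels.

`fluidvent` replaces the 3-D fluid dynamics of that device with a
lumped-parameter hybrid model, keeping exactly the features that define
its ventilator behavior: the two-state diverter, the pressure-threshold
switching, the screw-dependent resistances and thresholds, and the
single-compartment lung load.

## Model

**Lung (Windkessel).**  A resistance R_aw in series with a compliance C:

    P_alv(t) = Q·R_aw + V/C + P_peep + P_pl,   V = ∫ Q dt,

with all pressures gauge (atmosphere = 0) in cmH2O, V in L above the
end-expiratory baseline, Q in L/s.  P_alv is algebraic — only V is a
state — which avoids differential-algebraic machinery.  Presets:
R_aw = 3 cmH2O·s/L with C = 10 (fibrosis), 30 (healthy), 50 (emphysema)
mL/cmH2O.

**Diverter.**  A two-phase hysteresis switch.  During inspiration the
lung receives a constant fraction of the source flow,
Q = eta_insp·Q_src; the remainder vents through the side channel.
Constant-flow charging reflects the fixed 30 L/min supply and the
near-constant inspiratory durations it produces; alveolar pressure then
rises linearly.  During expiration the lung discharges through the
exhaust path: Q = −P_el/R_exp with P_el = V/C + P_peep + P_pl the
elastic/offset driving pressure and R_exp = R_EC(d_EC) + R_aw the total
expiratory resistance, so P_alv = Q·R_aw + P_el relaxes exponentially
toward atmosphere with time constant R_exp·C.  The phase flips
INSPIRATION→EXPIRATION when P_alv ≥ P_high and back when P_alv ≤ P_low;
P_high > P_low (hysteresis) guarantees a relaxation oscillation rather
than chatter.

**Screws.**  Occlusion fractions d ∈ [0, 1] map linearly onto channel
resistance, R(d) = R_open + R_span·d.  A linear law was chosen over a
diverging (1/(1−d)-type) law because the observed tuning behavior of
the physical device is a *linear* relationship between exhaust-screw
depth and oscillation period across the whole adjustment range; since
the period is affine in R_EC (see below), only an affine resistance law
reproduces that.  The FC and SC screws act on the switching thresholds
through affine maps (signs: closing SC raises PIP, closing FC lowers
it), returning (20, 8) cmH2O at the calibrated midpoint settings.  The
feedback channel's physical role (returning a small flow to the nozzle
to pre-bias the jet) is folded into the threshold map rather than
modeled as a flow path, because the switching it produces is
characterized entirely by the lung pressure at the transitions.

**Patient trigger.**  Inspiratory effort is a pleural-pressure step with
first-order dynamics, P_pl = −A(1 − e^{−(t−t0)/τ}), A = 3 cmH2O by
default (a `bench` profile of 5.5 cmH2O is provided, matching the
stronger muscle profiles used on hardware lung simulators) and
τ = R_aw·C of the active lung unless overridden.  Efforts start on a
fixed schedule (default: every 4 s) but only take effect during
expiration; efforts scheduled during inspiration are skipped, not
queued.  The effort ends — P_pl resets to 0 — the instant the diverter
answers with inspiration, since only the effect on switch timing is
modeled.  During expiration the effort lowers P_el and hence P_alv,
meeting the P_alv ≤ P_low switching condition early: a premature,
patient-triggered breath.

**Design calculator.**  The vortex-chamber fill time
Δt_c = πD²h/(4·v·ṁ) (equivalently chamber volume over volumetric flow)
estimates the oscillator's characteristic switching timescale at design
time; with the default 88 mm × 2.4 mm chamber and 30 L/min it gives
29.2 ms.

## Numerics

Fixed-step explicit midpoint (RK2), dt = 1 ms, over a 60 s horizon.
The in-phase dynamics are scalar linear ODEs, so RK2 at this step is
far inside its stability and accuracy region; a fixed deterministic
scheme makes reruns bit-identical (there is no randomness anywhere in
the simulator — only the fixture generator draws noise, from a seeded
generator).  Threshold crossings are located by bisection on the step
to within dt/100; the pre-switch state is recorded exactly at the
refined crossing time (the sample *at* a switch instant carries the
outgoing phase), so segmentation reads PIP and PEEP at the events
themselves rather than at grid points.  Verified properties: simulated
expirations track the closed-form RC discharge to ≤ 0.01 cmH2O;
recorded V agrees with the trapezoidal integral of recorded Q to within
10·dt·max|Q|; halving dt moves PIP/PEEP/period by < 0.5%.

Degenerate inputs: Q_src = 0 (or an unreachable threshold) produces a
diagnostic `NonOscillationError` naming the violated condition rather
than a silent flat record.  Threshold maps that would put P_high below
P_low anywhere on the admissible screw square are rejected at
configuration time.

## Calibration

Three constants of the reduced model are not physical inputs and were
fitted once (`scripts/calibrate.py`, a grid/bisection search over
simulations; the results are frozen as defaults and are not part of the
runtime path):

* `eta_insp = 0.69` sets the steady inspiratory time to ≈ 0.93 s.
  Because constant-flow charging makes T_i nearly independent of the EC
  screw, T_i is the single knob behind both ends of the I:E range: with
  T_i ≈ 0.93 s the expiratory-to-inspiratory ratio is ≈ 2.2 at the 3 s
  setting and ≈ 4.3 at the 5 s setting, inside the ±15% the "≈1:2" and
  "≈1:5" clinical targets imply.  (Exactly 1:2 and 1:5 simultaneously
  would require T_i to fall from 1.0 s to 0.83 s across the sweep,
  which constant-flow charging cannot produce; the near-constant-T_i
  compromise is the deliberate choice here.)
* `R_EC_open = 80.57` and `R_EC_span = 76.72` cmH2O·s/L put the mean
  steady period at 3.000 s (d_EC = 0) and 5.000 s (d_EC = 1) for the
  healthy preset, i.e. a tunable respiratory rate of 12–20 breaths/min.

Default problem sizes — 60 s horizon at dt = 1 ms (12–20 steady cycles
per run, first two discarded as transient) and an 11-point EC sweep —
are the package's standard study conditions; a full sweep takes a few
seconds on one core.

## The synthetic fixture generator

`make_synthetic_waveform` builds ventilator-shaped traces with *known*
indices for testing the analytics independently of the simulator: each
cycle rises exponentially from PEEP (asymptote chosen to hit PIP at
exactly T_i) and decays exponentially back (reaching PEEP at exactly
T_e), with optional seeded Gaussian noise and a companion flow trace
derived through a nominal compliance.  It emulates the waveform *shape*
and measurement noise of recorded pressure data; it does not emulate
trigger artifacts, baseline drift, cardiogenic oscillations or sensor
quantization, so analytics tests passing on fixtures demonstrate
correct index extraction, not robustness to every artifact of bench
recordings.

## Known limitations

* Single-compartment, linear lung: no volume-dependent compliance,
  inertance, airway collapse or multi-compartment heterogeneity.
* The diverter abstraction drops jet momentum, vortex strength,
  compressibility and feedback-channel transients; switching is exactly
  at the threshold pressures, so simulated PIP/PEEP are constant across
  EC settings to event-location accuracy (the physical device shows
  ~1 and ~3 cmH2O of variation).  The oscillation amplitude is the
  threshold difference P_high − P_low = 12 cmH2O by construction.
* A patient effort initiated *early* in expiration develops its full
  3 cmH2O before the switch; the following cycle's inspiration then
  starts with extra volume and its period can fall up to ~6% below
  steady state.  For efforts late in expiration (the characterized
  triggering regime, P_alv within ~3 cmH2O of PEEP) the post-trigger
  cycle stays within 5% on PIP, PEEP and period.
* Analytics define PEEP as the pressure at the expiration→inspiration
  switch (end-expiratory), not the cycle minimum; with a trigger dip the
  two differ.  SDs are sample SDs (n−1).
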