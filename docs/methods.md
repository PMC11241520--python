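# Methods

## Scope and model structure

`dsmcell` implements a single-compartment, deterministic model of an
isolated detrusor smooth muscle (DSM) cell. The membrane is a
parallel-conductance circuit: specific capacitance Cₘ in parallel with
eleven conductances, each in series with its reversal potential —
nine Hodgkin–Huxley-type channels (CaT, CaL, Kv1, KDR, KIR, KATP, SK,
IK, leak), a 10-state Markov BK channel and a TRPM4 channel — plus a
minimal intracellular Ca²⁺ pool. Gap-junction coupling, multicompartment
morphology, the muscarinic/IP₃/SR signalling cascade, pacemaking-type
activity and contraction mechanics are all out of scope; only the
endpoint of the Ca²⁺ cascade (free submembrane Ca²⁺ driving TRPM4,
BK, SK and IK) is represented.

Internal units are fixed: mV, ms, nA, pF, mM, S/cm², µA/cm². Every
config field carries its unit in its name, and unknown keys are
rejected naming the field and the expected unit.

### Geometry and passive membrane

Cylinder of length 200 µm and diameter 6 µm; lateral (open-cylinder)
area `π·d·L = 3.77·10⁻⁵ cm²`, end caps excluded by the usual
single-compartment convention. Specific constants: Cₘ = 1 µF/cm²
(37.7 pF total), Rₘ = 138 kΩ·cm² (leak conductance 7.25·10⁻⁶ S/cm²),
Rₐ = 183 Ω·cm (stored but unused — a single compartment carries no
axial current). The leak is treated as a depolarizing non-selective
background with reversal +50 mV (calibrated, see below); its
conductance is fixed by Rₘ.

## Channel formalism

### Hodgkin–Huxley gates

Each gate relaxes as `dm/dt = (m∞ − m)/τ` toward
`m∞(V) = 1/(1 + exp((V + V½)/S))`. The slope sign is explicit per
gate — negative for activation (rising sigmoid), positive for
inactivation — and is never flipped silently. Ca²⁺-gated channels
(SK, IK; optionally any gate) multiply the voltage factor by a Hill
term `1/(1 + (Ca½/Ca)ⁿ)`; SK and IK use a purely Ca²⁺-dependent gate.
Time constants may be constants or voltage-indexed tables with linear
interpolation (the shipped model uses constants). Currents are ohmic:
`I = ḡ·mˣ·hʸ·(V − E)`.

The KATP channel carries a constant `open_fraction` (0.35) multiplying
its conductance: its true gate — intracellular ATP — is outside the
model's scope, so its tonic openness is a fixed calibrated fraction of
the published maximum conductance.

### BK: 10-state Markov scheme

Five closed states C0–C4 and five open states O0–O4. Horizontal
transitions bind/unbind Ca²⁺ with the printed coefficients
(forward 3·K_on·Ca, 4·K_on·Ca, 3·K_on·Ca, K_on·Ca along each row;
backward K_off·Ca, 3·K_off·Ca, 4·K_off·Ca, 3·K_off·Ca with
K_coff = K_ooff = 26, K_on = 335). Vertical transitions use the
printed base rates multiplied by voltage factors `a = exp(V/a_efold)`
(opening) and `b = exp(−V/b_efold)` (closing); the O4→C4 rate carries
an additional Ca factor as printed. The functional form of `a` and `b`
is **a modelling choice of this package** — the source scheme leaves
them undefined — with e-fold slopes shipped at a_efold = 12 mV,
b_efold = 25 mV (calibrated) so that the channel is nearly closed at
rest and activates over the spike voltage range. Units of the rate
constants are treated as model-consistent (ms⁻¹, with Ca in mM).

Two deliberate oddities of the printed scheme are kept for fidelity
and must be understood when interpreting results:

1. **Ca²⁺-dependent unbinding.** Because every unbinding rate is also
   proportional to Ca, the ladder equilibria are Ca-independent; the
   only Ca-dependent equilibrium ratio is the O4↔C4 pair, whose
   *closing* rate grows with Ca. The stationary conducting probability
   therefore *decreases* with Ca²⁺ at fixed voltage (verified
   numerically over 10 nM–10 µM). Voltage dependence is normal
   (opening grows with depolarization).
2. **Conducting states.** The current sums O1–O4 (O0 excluded), per the
   printed definition; a `conducting_states` switch allows the
   O4-only reading for sensitivity checks.

Occupancies evolve by `dP/dt = QᵀP`. The stepper is a backward-Euler
linear solve (10×10) per step: unconditionally stable against the
stiff open→closed rates at hyperpolarized potentials and exactly
probability-conserving (columns of Qᵀ sum to zero). A dense matrix
exponential serves as the test oracle only. Being first-order, the
stepper tracks a cold-start transient only to O(dt); near steady state
(the regime of a running simulation) single steps agree with the
exponential to better than 10⁻⁶.

### TRPM4

A single activation gate (the printed steady-state variable and
kinetic gate are identified, since only one steady state and one τ are
given): `I = ḡ·m·(V − E_rev)` with E_rev = −40 mV, first-order
relaxation (τ = 10 ms, calibrated order-of-magnitude choice) toward
the Hill steady state in Ca²⁺. No inactivation gate is included — the
printed equations define none, though the accompanying text mentions
"activation and inactivation"; an inactivation slot exists in the
config and defaults to absent. Ca½ and n are free parameters fitted to
steady-state activation data (`fit_hill`); the shipped values
(Ca½ = 94.5 nM, n = 2) come from the whole-cell calibration and give a
resting activation of ≈0.73 at the resting Ca²⁺ of ≈154 nM.

### Intracellular Ca²⁺

One well-mixed submembrane shell:
`d[Ca]/dt = −I_Ca/(2F·d·(1+κ)) − ([Ca] − Ca_rest)/τ` with depth
d = 0.1 µm, rapid-buffering capacity κ = 400 (≈0.25 % of entering Ca²⁺
stays free — typical smooth-muscle buffering), extrusion τ = 20 ms and
Ca_rest = 150 nM. The update is the exact exponential step at frozen
current, floored at 10⁻⁹ mM with a logged warning. A `clamp` flag pins
the concentration at Ca_rest, reproducing a strictly maintained
resting Ca²⁺. A direct current-to-concentration factor can replace the
shell computation. All pool constants are calibrated, not published
values: the source model states no Ca²⁺-handling equations. The
resting level is taken as 150 nM; the source also prints "0.1 mM" at
rest once, presumed a µM/mM slip, and the 150 nM reading is adopted.

## Stimuli

**Square pulse.** Amplitude is a raw number in *stimulus units* with a
configurable conversion `unit_na` (0.4988 nA per unit in the shipped
config). Rationale: the published threshold amplitudes are printed in
mA, which is six orders of magnitude too large for a ~38 pF cell; the
simulator keeps the printed number as the reportable quantity and maps
it to a physically sane current through a calibrated scale. The
calibrated cell's true 10-ms rheobase is 0.277 nA.

**Alpha synapse.** `g(t) = g_peak·((t−t₀)/τ)·exp(1 − (t−t₀)/τ)`,
peaking at exactly g_peak one τ after onset; synaptic current
`g·(V − E_syn)`. E_syn = 0 mV (standard excitatory reversal) and
τ = 7.5 ms (calibrated; the source states neither).

## Integration

Operator splitting per step (default dt = 0.04 ms):

1. the Ca²⁺ pool advances using the Ca²⁺ channel currents of the
   current state;
2. all HH/TRPM4 gates relax exponentially toward their steady states at
   the frozen voltage and fresh Ca²⁺ (exact at frozen V);
3. BK occupancies advance by the backward-Euler solve;
4. the voltage advances by backward Euler — exact for the membrane
   equation, which is linear in V once gates are frozen.

The scheme is unconditionally stable, first-order accurate overall,
and self-convergent (halving dt changes subthreshold traces by far
less than the 0.5 mV acceptance band). Divergence (|V| > 200 mV) or a
non-finite voltage raises an integration error naming the failing
time. There is no randomness anywhere in the simulator: repeated runs
are bit-identical, and a run is the exact prefix of any longer run.

Initialization: gates at their steady states for V₀ = −52 mV, BK at
its stationary distribution, Ca at Ca_rest (`equilibrate: true`). A
cold start (`equilibrate: false`: gates closed, BK in C0) reproduces
the initial settling fluctuation of a freshly constructed model.

## AP feature extraction

- **RMP**: mean voltage over the last 100 ms before stimulus onset.
- **Spike detection**: a local maximum more than 30 mV above RMP whose
  preceding 10 ms contain dV/dt ≥ 5 mV/ms.
- **Threshold voltage**: the exit from the quiescent near-threshold
  crawl. From the upstroke dV/dt maximum the trace is walked backward
  to the last sample below the *onset criterion* (1.8 mV/ms,
  calibrated). Two naive alternatives fail: the first criterion
  crossing after stimulus onset misreads the passive deflection of a
  square pulse (whose onset slope at rheobase is ~7 mV/ms), and a
  walk-back from the *peak* misreads the notch left when a 10-ms pulse
  ends mid-upstroke. The published model states no threshold rule; the
  onset criterion is the free parameter of this operationalization and
  was set during whole-cell calibration.
- **AP duration**: time from the threshold crossing until voltage
  falls back below the threshold level (so sub-peak shoulder changes
  register in the duration).
- **AHP depth**: RMP minus the post-peak minimum.
- **Non-physiological flag**: the post-spike voltage fails to return
  within 10 mV of the pre-stimulus RMP within 500 ms of the peak, or a
  second regenerative spike occurs after the stimulus has ended.

`threshold_search` bisects on a fixed amplitude grid (amplitude for
pulses, peak conductance for synapses), requires a valid
non-spiking/spiking bracket, and returns the smallest spiking grid
point. Spike classification uses a 450-ms observation window
(300 ms after stimulus onset); near the threshold the spike latency
grows, so the window is part of the protocol definition.

## Calibration

The published model inherits its gating kinetics from earlier work
without reprinting them, so all half-potentials, slopes and time
constants here are free parameters. The calibration philosophy:

- every **maximum conductance** stays at its published value
  (CaT 2·10⁻⁴, CaL 3·10⁻⁴, Kv1 6·10⁻⁴, KDR 9·10⁻⁴, BK 8·10⁻⁴,
  IK 7·10⁻⁴, SK 1·10⁻⁴, KATP 1·10⁻⁴, KIR 1·10⁻⁴, TRPM4 2·10⁻⁴ S/cm²);
- the **kinetic free parameters** were tuned (deterministic bounded
  searches, `calibrate_cell`) against the published whole-cell
  targets: resting potential −52 mV sustained over 2000 ms; pulse
  threshold 0.56 stimulus units at 0.01 resolution (0.55 subthreshold);
  synaptic threshold 0.0079 µS at 0.0001 resolution (0.0078
  subthreshold); AP threshold voltages −38.56 mV (pulse) and
  −38.42 mV (synapse) within ±0.5 mV of each other.

The resulting functional architecture, stated explicitly because it is
a design outcome rather than published biophysics: CaT (steep
activation near −39.5 mV, slow inactivation) is the regenerative
takeoff current that sets the AP threshold; CaL (activation near
−34 mV) carries the upstroke; Kv1 acts as a low-threshold,
fast-inactivating (A-type-like) guard that makes the −52…−40 mV
corridor net-outward — it sets the stimulus thresholds and prevents
spontaneous firing — and inactivates above −40 mV to release the
spike; KDR is the high-voltage repolarizer; BK, nearly closed at rest
with the calibrated voltage factors, adds repolarizing drive at spike
voltages; SK/IK (Ca½ 1.2 µM) engage only on the spike Ca²⁺ transient
and shape the after-hyperpolarization; TRPM4 and the background leak
supply the standing depolarizing current that balances rest at
−52 mV. E_K is −70 mV and E_Ca is approximated by a fixed +50 mV
reversal.

Reversal potentials, the KATP open fraction, the BK e-folds, the
TRPM4 Hill pair, the Ca-pool constants, the stimulus unit scale, the
alpha-synapse τ and the onset criterion are all part of the calibrated
set and are tagged `calibrated` in the parameter provenance table
(`dsmcell.defaults.PROVENANCE`).

## Synthetic activation data

`synthetic_activation_curve` emulates digitized steady-state TRPM4
activation points: concentrations evenly spaced on the log₁₀-Ca axis
(default 10 nM – 10 µM), the Hill curve evaluated at known (Ca½, n),
i.i.d. Gaussian noise (default SD 0.02) and clipping to [0, 1],
deterministic per seed. It emulates the *shape and noise level* of
such experimental curves — a symmetric logistic in log-Ca with
homoscedastic digitization error. It does not emulate voltage- or
ATP-dependent modulation of TRPM4 activation, concentration-dependent
error bars, or systematic digitization bias, so parameter-recovery
results transfer to real activation data only insofar as those effects
are small.

Goodness of fit uses the degrees-of-freedom-corrected residual
`S = √(Σ(y_exp − y_sim)²/(M − N))` with the acceptance rule
*S strictly below 5 % of the experimental range*.

## Known limitations

- The BK conducting probability decreases with Ca²⁺ (a direct
  consequence of the printed Ca-dependent unbinding rates); the
  channel behaves as a voltage-activated K⁺ conductance whose Ca²⁺
  sensitivity has the opposite sign to canonical BK.
- TRPM4's influence on excitability is bounded by its published
  conductance and −40 mV reversal: between rest (−52 mV) and its
  reversal the driving force never exceeds 12 mV, so a ±20 % gmax
  change moves subthreshold currents by only ~20–30 pA — two orders
  below the AP currents and an order below the ~300 pA excitation
  barrier implied by the synaptic threshold. Within this calibration
  a 20 % TRPM4 increase therefore shifts the resting potential and AP
  shape smoothly but cannot trigger regenerative instability; the
  sweep reports it as a physiological AP.
- Spike latency diverges near threshold (a fold bifurcation), so
  threshold searches are defined jointly with their observation
  window.
- AP shape variability across real DSM cells is represented only
  through parameters; there is no stochastic channel gating and no
  temperature (Q10) correction.
- The model reproduces evoked spike-type APs; pacemaking-type firing
  and multicellular syncytium behaviour are out of scope.
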