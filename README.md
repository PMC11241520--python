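# dsmcell

A single-compartment biophysical simulator of the urinary bladder
**detrusor smooth muscle (DSM) cell**, built to study how the
Ca²⁺-activated TRPM4 cation channel shapes the cell's resting membrane
potential and action potentials — the cellular events behind overactive
bladder. It is aimed at computational electrophysiologists and
smooth-muscle researchers who want a scriptable, deterministic cell
model with explicit, unit-checked parameters.

## The model

The cell is a cylinder (200 µm × 6 µm; Rₘ = 138 kΩ·cm², Rₐ = 183 Ω·cm,
Cₘ = 1 µF/cm², ≈37.7 pF) carrying a parallel-conductance membrane:

- **Nine Hodgkin–Huxley-type conductances** — T- and L-type Ca²⁺
  channels, fast (Kv1), delayed-rectifier (KDR), inward-rectifier
  (KIR) and ATP-sensitive (KATP) K⁺ channels, small- and
  intermediate-conductance Ca²⁺-activated K⁺ channels (SK, IK), and an
  ohmic leak. Each gate obeys `dm/dt = (m∞(V, Ca) − m)/τ` with
  Boltzmann voltage dependence `m∞ = 1/(1 + exp((V + V½)/S))` and,
  where Ca²⁺-gated, a Hill factor `1/(1 + (Ca½/Ca)ⁿ)`.
- **A 10-state Markov BK channel** (C0–C4 ↔ O0–O4) with
  Ca²⁺-dependent binding ladders and voltage-dependent open/close
  transitions; current `I_BK = ḡ·(O1+O2+O3+O4)·(V − E_K)`.
- **TRPM4**, a Ca²⁺-activated non-selective cation channel:
  `I = ḡ·m·(V − E_rev)` with `E_rev = −40 mV` and Hill steady-state
  activation in intracellular Ca²⁺.
- **A minimal Ca²⁺ pool** (submembrane shell with rapid buffering and
  first-order extrusion to a 150 nM resting level) that couples the
  Ca²⁺ currents to BK/SK/IK/TRPM4.

Integration is operator-split at dt = 0.04 ms: exact exponential
updates for the gates, a backward-Euler linear solve for the BK
occupancies, and backward Euler for the (conditionally linear) membrane
equation. Everything is deterministic — identical inputs give
bit-identical traces.

The maximum conductances are the published per-channel values; the
gating kinetics the source model never printed are free parameters,
calibrated once (see `docs/methods.md`) so that the assembled cell
reproduces the published whole-cell numbers: a −52 mV resting
potential held over 2 s, a 10-ms pulse threshold of 0.56 stimulus
units, a synaptic (alpha-function) threshold of 0.0079 µS, and an AP
threshold voltage near −38.5 mV.

## Worked example

```python
import dsmcell as d
from dsmcell.experiments import default_model, pulse_template, threshold_voltage

model, cfg = default_model()
amp = d.pulse_threshold(model, cfg, lo=0.4, hi=0.8, resolution=0.01)
feats = threshold_voltage(model, cfg, pulse_template(cfg, amplitude=amp))
print(f"pulse threshold : {amp:.2f} stimulus units")
print(f"AP threshold    : {feats.threshold_v_mv:.2f} mV")
print(f"AP peak         : {feats.peak_v_mv:.2f} mV")
print(f"AP duration     : {feats.ap_duration_ms:.1f} ms")
print(f"AHP depth       : {feats.ahp_depth_mv:.2f} mV")
```

prints

```
pulse threshold : 0.56 stimulus units
AP threshold    : -38.68 mV
AP peak         : -18.16 mV
AP duration     : 54.7 ms
AHP depth       : 5.13 mV
```

i.e. the smallest 10-ms current pulse (on the 0.01-unit bisection
grid) that fires the cell is 0.56 stimulus units; the spike takes off
at −38.68 mV, peaks at −18.2 mV, lasts ~55 ms at the threshold level
and undershoots rest by ~5 mV — a slow, low-amplitude Ca²⁺ spike
typical of detrusor muscle.

The same protocols are available from the shell:

```bash
dsmcell simulate --out trace.csv                 # 2-s resting run, CSV + manifest
dsmcell threshold-search --kind pulse --lo 0.1 --hi 1.2 --resolution 0.01
dsmcell sweep --channel trpm4 --from 0.7 --to 1.2 --steps 6
dsmcell knockout --mute cat --compensate comp.yaml
dsmcell fit-activation --data points.csv
```

Model and protocol parameters live in a single YAML config mirroring
`dsmcell.defaults.default_config()`; unknown keys are rejected with the
field name and expected unit.

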