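# ca1pyr

Point-neuron models of CA1 pyramidal cells: deterministic simulation,
electrophysiological characterization, and quantitative, RMSE-scored
validation of model implementations.

## The models

The package implements an adaptive quadratic integrate-and-fire
(modified Izhikevich) description of a CA1 pyramidal cell. The state is
a fast membrane potential *V* (mV) and a slow recovery current *u*
(pA):

    C_m dV/dt = k (V − v_r)(V − v_t) − u + I_ext + I_shift
      du/dt   = a [ b (V − v_r) − u ]

    if V ≥ v_peak:  V ← c,  u ← u + d

    k = k_low  if V ≤ v_t,   k = k_high  if V > v_t

The split quadratic gain lets a single parameter set capture both the
shallow subthreshold current–voltage relation and the sharp spike
upstroke. Three built-in variants differ only in their constants: a
strongly adapting cell (`Pyr_Strong`) and two weakly adapting cells
(`Pyr_Weak1`, `Pyr_Weak2`; the latter has a recovery time constant
1/a = 12.5 s). `I_ext` is a square current pulse, active on the
half-open window [t_start, t_stop). Integration is forward Euler at a
fixed 0.02 ms step from a fixed initial state (−65 mV, 0 pA by
default); there is no randomness anywhere, so every run is
bit-reproducible.

On top of the simulator the package provides:

* **features** — the standard trace features: initial/final ISI
  frequencies (1000/ISI, with the single-spike → 1 Hz convention),
  spike count and latencies, AP amplitude and half-width, steady-state
  voltage deflection. All values are rounded to two decimals.
* **characterization** — f-I curves (−50..300/350 pA in 10 pA steps),
  rheobase (1 pA linear scan), hyperpolarizing I-V curves (onset
  1,500 ms, offset 4,000 ms, total 5,000 ms) and input resistance.
* **validation** — a model-agnostic capability contract (arm a square
  current, run and record somatic voltage, reset), reference-data
  files, and suites that score any conforming implementation against
  reference data with per-feature RMSE in the feature's own units. A
  faithful re-implementation scores an all-zero table against the
  built-in reference simulator.

## Worked example

```python
import ca1pyr as c

p = c.variant_parameters("Pyr_Strong")
res = c.simulate(p, c.StimulusProtocol(amplitude=250.0, t_start=0.0,
                                       t_stop=1000.0, t_total=1000.0))
ini, fin = c.spike_frequencies(res.spike_times)
print(f"{res.n_spikes} spikes; initial {c.round2(ini)} Hz, final {c.round2(fin)} Hz")

rin = c.input_resistance(c.iv_curve(p))
print(f"input resistance: {rin.value:.1f} MOhm ({rin.convention}, {rin.n_points} points)")
```

prints

```
41 spikes; initial 107.3 Hz, final 24.69 Hz
input resistance: 224.5 MOhm (current_window, 3 points)
```

i.e. under a 250 pA, 1 s pulse the strongly adapting cell starts firing
at ≈107 Hz and adapts down to ≈25 Hz, and its passive input resistance
— the slope of the voltage-deflection-versus-current line over the
−10..−30 pA battery points — is 224.5 MΩ.

The same is available from the shell:

```
$ ca1pyr simulate -v Pyr_Strong -a 188 --t-stop 1000 --t-total 1000 -o out/
31 spikes; trace bundle in out
$ ca1pyr characterize rheobase -v Pyr_Weak2
rheobase(Pyr_Weak2) = 49.0 pA
$ ca1pyr make-reference -o reference.json && ca1pyr validate -r reference.json
```

Subcommands: `simulate`, `characterize (fi | rheobase | iv)`,
`features`, `make-reference`, `validate`. Every command logs its fully
resolved configuration and dumps it as `run_config.yaml` next to its
outputs; a saved configuration re-executes to identical results.

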