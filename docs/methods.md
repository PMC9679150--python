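# Methods

## Model

The cell is a two-variable hybrid dynamical system — an adaptive
quadratic integrate-and-fire (modified Izhikevich) point neuron. With
units fixed to mV, ms, pA, pF and nS,

    C_m dV/dt = k (V − v_r)(V − v_t) − u + I_ext + I_shift
      du/dt   = a [ b (V − v_r) − u ]
    reset:      if V ≥ v_peak then V ← c, u ← u + d
    gain:       k = k_low if V ≤ v_t, else k_high

every term of the voltage equation is in pA and no unit-conversion
constants appear anywhere in the integrator. The gain switch at the
threshold potential `v_t` (boundary assigned to `k_low`) gives the model
a realistically shallow subthreshold I-V relation together with a sharp
spike upstroke; `I_shift` shifts the f-I curve laterally without
touching the dynamics' shape.

Built-in variants (all share v_r = −61.8 mV, v_t = −57.0 mV,
c = −65.8 mV, v_peak = 22.6 mV, k_high = 3.3 nS/mV, b = 3 nS):

| parameter | Pyr_Strong | Pyr_Weak1 | Pyr_Weak2 |
|---|---|---|---|
| C_m (pF) | 115 | 300 | 300 |
| a (1/ms) | 0.0012 | 0.001 | 0.00008 |
| d (pA) | 10 | 5 | 5 |
| k_low (nS/mV) | 0.1 | 0.5 | 0.5 |
| I_shift (pA) | 0 | −45 | −45 |

`Pyr_Strong` adapts strongly (large d, fast recovery); the weak
variants differ only in the recovery rate a, giving `Pyr_Weak2` a
recovery time constant 1/a = 12.5 s — far slower than any protocol
used here, which matters for its passive measurements (below). The
registry is immutable; copies for perturbation experiments are made
with `ModelParameters.replace`. The same parameter sets can be dumped
to and loaded from YAML/JSON.

## Integration and recording conventions

* Forward Euler, fixed step dt = 0.02 ms by default. The total
  duration must be an integer multiple of dt (to 1e-9 relative
  tolerance); silent truncation is an error.
* Both derivatives are evaluated at the same pre-step state, and the
  gain k is chosen from the pre-step voltage.
* The stimulus is a square pulse, active on the half-open window
  [t_start, t_stop); the current at a sample time multiplies the full
  following step.
* When a step's raw update reaches `v_peak`, the crossing sample
  records the **raw overshoot** voltage (so trace-based feature
  extraction sees a detectable peak) and the reset state (c, u + d)
  takes effect from the next sample. The spike time is the grid time
  of the crossing sample; no sub-step interpolation.
* Initial state: V = −65.0 mV, u = 0 pA. The original published code
  drew the initial potential uniformly from [−75, −55] mV; for
  reproducibility this package fixes the mean value, and alternative
  initial potentials (−55, −61.8, −75 mV) are plain configuration
  overrides. u₀ is not specified anywhere in the source material; 0 pA
  is the common convention, and subthreshold equilibration during the
  pre-stimulus or early-stimulus window absorbs the choice in every
  protocol used here.
* A non-finite state raises a numerical-instability error naming the
  offending time, current and variant. There is no randomness anywhere:
  repeated runs are bit-identical.

An analytic oracle accompanies the integrator: with u on its nullcline
u = b (V − v_r), subthreshold equilibria solve
k_low x² + (k_low (v_r − v_t) − b) x + I + I_shift = 0 with
x = V − v_r, and the stable root is the one with negative slope of the
voltage equation's right-hand side. For the weak variants at I = 0 this
gives x² − 10.8x − 90 = 0, i.e. a rest of −67.32 mV; the strongly
adapting cell rests exactly at v_r = −61.8 mV. Long simulations agree
with the oracle to 0.1 mV (0.5 mV for `Pyr_Weak2`, which needs ~30 s of
simulated time to settle because 1/a = 12.5 s).

## Feature extraction

Twelve named features are extracted from (times, vm, spike_times,
stim_start, stim_end) bundles. Initial/final frequency are the inverses
of the first/last ISI (1000/ISI ms → Hz); a single spike maps to
(1, 1) Hz by convention, and no spikes to (0, 0) Hz (the natural
no-activity encoding, matching the flat segments of published f-I
curves). Spike latencies are measured from stimulus onset; a missing
spike yields an undefined marker (NaN), never an exception, so
validation can exclude it pairwise.

AP amplitude and half-width are defined on the trace: the onset is the
first sample whose forward-difference dV/dt exceeds 20 mV/ms rising
into the spike (a common extraction default; configurable), the peak is
the trace maximum between that onset and the next spike's onset, the
amplitude their difference, and the half-width the time between the
linearly interpolated crossings of onset + amplitude/2. Because the
reset makes the downstroke a one-sample discontinuity, the downward
crossing interpolates across that jump — a property of any fixed-step
trace, shared by the reference recordings such features would be
compared against.

Voltage deflection = mean(vm over the last 10% of the stimulus window)
− mean(vm over the last 100 ms before onset). The I-V protocol's
1,500 ms pre-stimulus and 2,500 ms pulse make both windows stable for
all variants except the slow-recovery tail of `Pyr_Weak2`, which is
accepted as-measured (the same finite-duration measurement any
current-clamp characterization would report).

Every stored feature value is rounded to two decimals,
half-away-from-zero, exactly once — at the feature level, never inside
the integrator.

## Characterization protocols

* **f-I**: 1,000 ms pulse from t = 0 per current; default grids
  −50..300 pA (strong) / −50..350 pA (weak) in 10 pA steps.
* **Rheobase**: linear upward scan in 1 pA steps over [−60, 100] pA by
  default, so the depolarized-initial-potential experiments run without
  reconfiguration. The scan is linear, not bisection: with a
  depolarized initial state the spiking set need not be an upper
  half-line. Each candidate pulse lasts 2,000 ms: near threshold the
  first spike can lag onset by more than 1 s (e.g. `Pyr_Weak2` at
  49 pA fires at ≈1,078 ms), so a 1 s pulse would overstate the
  rheobase by 1 pA.
* **I-V**: hyperpolarizing battery 0..−400 pA in 10 pA steps; onset
  1,500 ms, offset 4,000 ms, total 5,000 ms. A spike at or before
  offset is a protocol violation; spikes after offset are tolerated —
  the excitable variants fire rebound spikes on release from even a
  −10 pA step, and the deflection windows close at offset.
* **Input resistance**: the slope of deflection against current is
  evaluated under three conventions, reported side by side. The
  calibrated primary convention is the least-squares slope over the
  battery points with current in [−30, −10] pA (224.5 / 80.5 /
  86.5 MΩ for the three variants). The alternative readings — slope
  restricted to deflections in [−30, −10] mV, and the point ratio at
  the −10 mV deflection — give materially different values
  (≈133 MΩ and ≈229 MΩ for `Pyr_Strong`) and are retained because the
  conventional phrase "evaluated between −10 and −30" does not pin the
  axis; only the current-window reading is consistent across all three
  variants at once.

## Validation

Models are scored through a minimal somatic current-clamp capability:
`reset_model()`, `inject_soma_square_current(protocol)`,
`get_soma_vm(t_stop)`, plus the composed `run_stim_get_vm`. The
contract requires reset-reproducibility (two identical runs after reset
must be bit-identical), which the suite verifies once per adapter.

A test evaluates one feature over a stimulus grid (reset + stimulate
per current), rounds to two decimals, and scores against reference data
with RMSE in the feature's units. RMSE is computed on the rounded
values (references are stored rounded, so scoring unrounded predictions
would fabricate disagreement). Grid points where the feature is
undefined on either side are excluded pairwise rather than scored as
agreement. Reference files (JSON or tidy CSV, schema-versioned) are
generated by the built-in simulator.

Suite levels mirror the two natural tiers of such comparisons: level I
scores initial/final frequency over the full f-I grids; level II scores
spike count, three spike latencies, three AP amplitudes, three AP
half-widths (suprathreshold grids: 100..300/350 pA in 50 pA steps,
chosen so every spike feature is defined at every point) and the
per-point I-V resistance (−10, −50, −100, −150, −200 pA). The built-in
adapter scored against its own freshly generated fixtures yields an
all-zero table; a candidate integrated at dt = 0.04 ms against
dt = 0.02 ms references reproduces the expected error-accumulation
signature (spike-time RMSE growing from first to second to last spike).

## Design choices where the ground was open

* Rheobase pulse length (2,000 ms) — chosen for the near-threshold
  latency reason above.
* Zero-spike frequency encoding (0 Hz), onset-slope threshold
  (20 mV/ms), deflection windows (last 100 ms baseline / last 10% of
  pulse), level-II grids — all documented defaults, all configurable.
* RMSE on rounded values; undefined features excluded pairwise.
* The trace's crossing sample stores the overshoot rather than the
  reset value — frequencies, rheobase and deflections are insensitive
  to this choice; AP amplitude is not, which is one reason amplitude
  comparisons across integrators are the least portable feature here.

## Limitations

* Forward Euler with the reset rule is first-order and
  discretization-sensitive: spike times shift by O(dt) per spike and
  the error accumulates along the train (measured: halving dt changes
  the 250 pA initial/final frequencies of `Pyr_Strong` by <0.3%, but a
  coarser dt visibly inflates time-to-last-spike RMSE). All published
  comparisons here are defined at dt = 0.02 ms.
* The model is a point neuron: no morphology, no synapses, no channel
  noise; AP shape is a by-product of the reset rule, not a modeling
  target.
* `Pyr_Weak2`'s 12.5 s recovery time constant means none of the
  protocols observe its true steady state; its I-V deflections are
  systematically more negative than the u-nullcline prediction (the
  frozen recovery current removes the stabilizing b-feedback), and its
  "final" frequency still drifts at the 1 s pulse end.
* Validation compares implementations against reference data generated
  by this package's own simulator; it measures implementation fidelity,
  not biological accuracy.
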