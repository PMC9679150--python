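"""Adaptive quadratic integrate-and-fire models of CA1 pyramidal cells.

The cell is a two-variable hybrid dynamical system: a fast membrane
potential ``V`` (mV) with a quadratic current-voltage nonlinearity, and a
slow recovery current ``u`` (pA),

    C_m dV/dt = k (V - v_r)(V - v_t) - u + I_ext + I_shift
      du/dt   = a [ b (V - v_r) - u ]

with a discontinuous reset when ``V`` reaches the spike cut-off
``v_peak``: ``V <- c``, ``u <- u + d``.  The quadratic gain ``k`` switches
between ``k_low`` (for ``V <= v_t``) and ``k_high`` (for ``V > v_t``),
which lets a single parameter set capture both the shallow subthreshold
I-V relation and a sharp spike upstroke.

Units are fixed throughout the package: mV, ms, pA, pF, nS.  With this
choice every term of the voltage equation is in pA and no conversion
constants appear in the integrator.

Three built-in parameter sets describe a strongly adapting CA1 pyramidal
cell (``Pyr_Strong``) and two weakly adapting ones (``Pyr_Weak1``,
``Pyr_Weak2``).  Integration is forward Euler with a fixed step
(default 0.02 ms); there is no randomness anywhere, so repeated runs are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "StimulusProtocol",
    "SimulationConfig",
    "NeuronState",
    "SimulationResult",
    "EulerStep",
    "UnknownVariantError",
    "NumericalInstabilityError",
    "NoSubthresholdEquilibrium",
    "VARIANT_NAMES",
    "variant_parameters",
    "variant_registry",
    "applied_current",
    "euler_step",
    "simulate",
    "subthreshold_fixed_point",
    "dump_variants",
    "load_variants",
    "write_trace_bundle",
]


class UnknownVariantError(KeyError):
    """Requested cell variant is not in the registry."""


class NumericalInstabilityError(ArithmeticError):
    """The forward-Euler update produced a non-finite state."""


class NoSubthresholdEquilibrium(ValueError):
    """No real subthreshold fixed point exists for the given current."""


@dataclass(frozen=True)
class ModelParameters:
    """The eleven constants defining one cell variant.

    Parameters
    ----------
    name : str
        Variant label (e.g. ``"Pyr_Strong"``).
    v_r : float
        Resting membrane potential parameter, mV.
    v_t : float
        Spike threshold potential, mV.
    c : float
        Post-spike voltage reset, mV.
    v_peak : float
        Spike cut-off voltage, mV.
    k_low, k_high : float
        Quadratic gain below / above ``v_t``, nS/mV.
    C_m : float
        Membrane capacitance, pF.
    a : float
        Recovery-current rate constant, 1/ms (``tau_u = 1/a``).
    b : float
        Sensitivity of the recovery current to subthreshold voltage, nS.
    d : float
        After-spike increment of the recovery current, pA.
    I_shift : float
        Constant current laterally shifting the f-I curve, pA.
    """

    name: str
    v_r: float
    v_t: float
    c: float
    v_peak: float
    k_low: float
    k_high: float
    C_m: float
    a: float
    b: float
    d: float
    I_shift: float

    def __post_init__(self) -> None:
        if not self.C_m > 0:
            raise ValueError(f"C_m must be positive, got {self.C_m}")
        if not (self.k_high >= self.k_low > 0):
            raise ValueError(
                f"need k_high >= k_low > 0, got k_low={self.k_low}, k_high={self.k_high}"
            )
        if self.a < 0:
            raise ValueError(f"a must be non-negative, got {self.a}")
        if not (self.v_r < self.v_t < self.v_peak):
            raise ValueError(
                f"need v_r < v_t < v_peak, got {self.v_r}, {self.v_t}, {self.v_peak}"
            )
        if not self.c < self.v_peak:
            raise ValueError(f"reset c must lie below v_peak, got c={self.c}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with some fields changed (the registry is untouched)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class StimulusProtocol:
    """A square current pulse within a simulated window.

    The stimulus current equals ``amplitude`` (pA, either sign) on the
    half-open interval ``[t_start, t_stop)`` and 0 elsewhere.
    """

    amplitude: float
    t_start: float
    t_stop: float
    t_total: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_start < self.t_stop <= self.t_total):
            raise ValueError(
                "need 0 <= t_start < t_stop <= t_total, got "
                f"[{self.t_start}, {self.t_stop}) in {self.t_total} ms"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings: fixed time step and initial state.

    ``dt`` defaults to 0.02 ms.  The initial membrane potential defaults
    to -65.0 mV (the fixed value replacing the variable initial potential
    of the original published code) and the initial recovery current to
    0 pA, a conventional choice the model equilibrates away during any
    pre-stimulus or early-stimulus window.
    """

    dt: float = 0.02
    v_init: float = -65.0
    u_init: float = 0.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class NeuronState(NamedTuple):
    """Instantaneous model state: membrane potential V (mV), recovery u (pA)."""

    V: float
    u: float


class EulerStep(NamedTuple):
    """Result of one forward-Euler update.

    ``state`` is the post-step state (already reset if a spike occurred),
    ``spiked`` flags a reset, and ``v_raw`` is the un-clamped voltage the
    update produced, which exceeds ``v_peak`` on a spiking step.  Traces
    record ``v_raw`` so a detectable peak survives for feature extraction.
    """

    state: NeuronState
    spiked: bool
    v_raw: float


@dataclass(frozen=True)
class SimulationResult:
    """A uniformly sampled membrane-potential trace plus spike times.

    ``times`` is the grid ``0, dt, 2*dt, ...``; ``vm`` the recorded
    membrane potential (the raw overshoot at a spike's crossing sample,
    the reset value from the next sample on); ``spike_times`` the grid
    times at which the cut-off crossing was detected, strictly
    increasing.
    """

    times: np.ndarray
    vm: np.ndarray
    spike_times: np.ndarray
    protocol: StimulusProtocol
    config: SimulationConfig
    params: ModelParameters

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def as_feature_input(self):
        """Bundle the trace for feature extraction (times, vm, spikes, window)."""
        from .features import FeatureInput

        return FeatureInput(
            times=self.times,
            vm=self.vm,
            spike_times=self.spike_times,
            stim_start=self.protocol.t_start,
            stim_end=self.protocol.t_stop,
        )


# --- variant registry -------------------------------------------------------

_COMMON = dict(v_r=-61.8, v_t=-57.0, c=-65.8, v_peak=22.6, k_high=3.3, b=3.0)

_REGISTRY: dict[str, ModelParameters] = {
    "Pyr_Strong": ModelParameters(
        name="Pyr_Strong", C_m=115.0, a=0.0012, d=10.0, k_low=0.1, I_shift=0.0,
        **_COMMON,
    ),
    "Pyr_Weak1": ModelParameters(
        name="Pyr_Weak1", C_m=300.0, a=0.001, d=5.0, k_low=0.5, I_shift=-45.0,
        **_COMMON,
    ),
    "Pyr_Weak2": ModelParameters(
        name="Pyr_Weak2", C_m=300.0, a=0.00008, d=5.0, k_low=0.5, I_shift=-45.0,
        **_COMMON,
    ),
}

VARIANT_NAMES: tuple[str, ...] = tuple(_REGISTRY)

_ALIASES = {
    "pyr_strong": "Pyr_Strong",
    "strong": "Pyr_Strong",
    "strongly_adapting": "Pyr_Strong",
    "pyr_weak1": "Pyr_Weak1",
    "weak1": "Pyr_Weak1",
    "weakly_adapting_#1": "Pyr_Weak1",
    "pyr_weak2": "Pyr_Weak2",
    "weak2": "Pyr_Weak2",
    "weakly_adapting_#2": "Pyr_Weak2",
}


def _normalize(name: str) -> str:
    return "_".join(name.strip().lower().replace("-", " ").split())


def variant_parameters(name: str) -> ModelParameters:
    """Look up a built-in cell variant by name (case-insensitive).

    Raises
    ------
    UnknownVariantError
        If ``name`` is not a known variant; the message lists valid names.
    """
    key = _ALIASES.get(_normalize(name))
    if key is None:
        raise UnknownVariantError(
            f"unknown variant {name!r}; valid names: {', '.join(VARIANT_NAMES)}"
        )
    return _REGISTRY[key]


def variant_registry() -> dict[str, ModelParameters]:
    """A copy of the built-in registry (mutating it never alters the built-ins)."""
    return dict(_REGISTRY)


_PARAM_KEYS = ("v_r", "v_t", "c", "v_peak", "k_high", "C_m", "a", "b", "d",
               "k_low", "I_shift")

_CONFIG_HEADER = (
    "Cell-variant parameter sets for the adaptive quadratic "
    "integrate-and-fire CA1 pyramidal cell model.\n"
    "Units: v_r, v_t, c, v_peak in mV; k_low, k_high in nS/mV; C_m in pF; "
    "a in 1/ms; b in nS; d, I_shift in pA."
)


def dump_variants(path, variants: Mapping[str, ModelParameters] | None = None) -> None:
    """Write a variant registry to YAML or JSON (by file extension)."""
    variants = variants if variants is not None else _REGISTRY
    payload = {
        name: {k: p.to_dict()[k] for k in _PARAM_KEYS}
        for name, p in variants.items()
    }
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path, "w") as fh:
            for line in _CONFIG_HEADER.splitlines():
                fh.write(f"# {line}\n")
            yaml.safe_dump(payload, fh, sort_keys=False)
    else:
        with open(path, "w") as fh:
            json.dump({"_comment": _CONFIG_HEADER, **payload}, fh, indent=2)


def load_variants(path) -> dict[str, ModelParameters]:
    """Read a variant registry written by :func:`dump_variants`."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            payload = json.load(fh)
    payload.pop("_comment", None)
    out = {}
    for name, fields in payload.items():
        missing = [k for k in _PARAM_KEYS if k not in fields]
        if missing:
            raise ValueError(f"variant {name!r} is missing parameters: {missing}")
        out[name] = ModelParameters(name=name, **{k: float(fields[k]) for k in _PARAM_KEYS})
    return out


# --- stimulus ---------------------------------------------------------------

def applied_current(protocol: StimulusProtocol, t: float) -> float:
    """External current at time ``t``: amplitude on [t_start, t_stop), else 0.

    Raises ``ValueError`` if ``t`` lies outside ``[0, t_total]``.
    """
    if not (0 <= t <= protocol.t_total):
        raise ValueError(
            f"t={t} outside the simulated window [0, {protocol.t_total}] ms"
        )
    if protocol.t_start <= t < protocol.t_stop:
        return protocol.amplitude
    return 0.0


# --- integration ------------------------------------------------------------

def euler_step(
    state: NeuronState,
    params: ModelParameters,
    I_ext: float,
    dt: float,
) -> EulerStep:
    """One forward-Euler update of (V, u), with the spike-reset rule.

    The quadratic gain is chosen from the pre-step voltage (``k_low`` iff
    ``V <= v_t``) and both derivatives are evaluated at the same pre-step
    state.  If the raw update reaches ``v_peak`` the returned state is
    ``(c, u' + d)`` and ``spiked`` is set.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    V, u = state
    p = params
    k = p.k_low if V <= p.v_t else p.k_high
    v_raw = V + dt * ((k * (V - p.v_r) * (V - p.v_t) - u + I_ext + p.I_shift) / p.C_m)
    u_new = u + dt * (p.a * (p.b * (V - p.v_r) - u))
    if not (math.isfinite(v_raw) and math.isfinite(u_new)):
        raise NumericalInstabilityError(
            f"non-finite update from V={V}, u={u}, I_ext={I_ext}, dt={dt} "
            f"({p.name})"
        )
    if v_raw >= p.v_peak:
        return EulerStep(NeuronState(p.c, u_new + p.d), True, v_raw)
    return EulerStep(NeuronState(v_raw, u_new), False, v_raw)


def _grid_steps(t_total: float, dt: float) -> int:
    n = round(t_total / dt)
    if n < 1 or abs(n * dt - t_total) > 1e-9 * max(1.0, abs(t_total)):
        raise ValueError(
            f"t_total={t_total} ms is not an integer multiple of dt={dt} ms"
        )
    return n


def _window_indices(protocol: StimulusProtocol, dt: float) -> tuple[int, int]:
    # half-open [t_start, t_stop): current is on at sample n iff
    # t_start <= n*dt < t_stop, with a 1e-9 guard against float drift
    i_on = math.ceil(protocol.t_start / dt - 1e-9)
    i_off = math.ceil(protocol.t_stop / dt - 1e-9)
    return i_on, i_off


def simulate(
    params: ModelParameters,
    protocol: StimulusProtocol,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Integrate the model over ``[0, t_total]`` under a square pulse.

    The sample at the grid time of a cut-off crossing records the raw
    (un-clamped) overshoot voltage; the reset state takes effect from the
    following sample.  Spike times are the grid times of the crossing
    samples — no sub-step interpolation.  The run is fully deterministic:
    identical inputs give bit-identical traces.
    """
    config = config or SimulationConfig()
    dt = config.dt
    n_steps = _grid_steps(protocol.t_total, dt)
    i_on, i_off = _window_indices(protocol, dt)
    amp = protocol.amplitude

    times = np.arange(n_steps + 1) * dt
    vm = np.empty(n_steps + 1)
    vm[0] = config.v_init

    # locals for speed; same arithmetic as euler_step, in the same order
    v_r = params.v_r
    v_t = params.v_t
    c = params.c
    v_peak = params.v_peak
    k_low = params.k_low
    k_high = params.k_high
    C_m = params.C_m
    a = params.a
    b = params.b
    d = params.d
    I_shift = params.I_shift

    V = config.v_init
    u = config.u_init
    spike_idx: list[int] = []
    for n in range(n_steps):
        I = amp if i_on <= n < i_off else 0.0
        k = k_low if V <= v_t else k_high
        v_raw = V + dt * ((k * (V - v_r) * (V - v_t) - u + I + I_shift) / C_m)
        u = u + dt * (a * (b * (V - v_r) - u))
        vm[n + 1] = v_raw
        if v_raw >= v_peak:
            spike_idx.append(n + 1)
            V = c
            u = u + d
        else:
            V = v_raw

    if not (np.isfinite(vm).all() and math.isfinite(u)):
        bad = int(np.flatnonzero(~np.isfinite(vm))[0]) if not np.isfinite(vm).all() else n_steps
        raise NumericalInstabilityError(
            f"non-finite membrane potential at t={bad * dt} ms "
            f"({params.name}, amplitude={amp} pA, dt={dt} ms)"
        )

    spike_times = times[spike_idx] if spike_idx else np.empty(0)
    return SimulationResult(
        times=times, vm=vm, spike_times=spike_times,
        protocol=protocol, config=config, params=params,
    )


# --- analytic oracle --------------------------------------------------------

def subthreshold_fixed_point(params: ModelParameters, I: float = 0.0) -> float:
    """Stable subthreshold resting potential under a constant current, mV.

    With ``u`` on its nullcline ``u = b (V - v_r)`` and ``x = V - v_r``,
    equilibria solve ``k_low x^2 + (k_low (v_r - v_t) - b) x + I + I_shift
    = 0``.  The stable root is the one where the slope of the voltage
    equation's right-hand side (``2 k_low x + k_low (v_r - v_t) - b``) is
    negative.  Used as a closed-form oracle for simulated steady states
    and voltage deflections.

    Raises
    ------
    NoSubthresholdEquilibrium
        If no real root exists (current above the saddle-node), or the
        stable root lies above ``v_t`` where the ``k_low`` branch no
        longer applies.
    """
    p = params
    A = p.k_low
    B = p.k_low * (p.v_r - p.v_t) - p.b
    Cc = I + p.I_shift
    disc = B * B - 4 * A * Cc
    if disc < 0:
        raise NoSubthresholdEquilibrium(
            f"no subthreshold equilibrium for {p.name} at I={I} pA"
        )
    sq = math.sqrt(disc)
    for x in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
        if 2 * A * x + B < 0:
            V = p.v_r + x
            if V > p.v_t:
                break
            return V
    raise NoSubthresholdEquilibrium(
        f"stable equilibrium for {p.name} at I={I} pA lies above v_t"
    )


# --- trace export -----------------------------------------------------------

def write_trace_bundle(result: SimulationResult, basepath) -> tuple[str, str]:
    """Write a trace as ``<base>.csv`` + ``<base>.json`` sidecar.

    The CSV holds two columns (time_ms, vm_mV); the JSON sidecar carries
    spike times, the stimulus protocol and the simulation config, so the
    bundle has everything a trace-based feature extractor needs
    (time, voltage, stim_start, stim_end).
    """
    base = str(basepath)
    csv_path, json_path = base + ".csv", base + ".json"
    arr = np.column_stack([result.times, result.vm])
    np.savetxt(csv_path, arr, delimiter=",", header="time_ms,vm_mV",
               comments="", fmt="%.6f")
    sidecar = {
        "spike_times_ms": [float(t) for t in result.spike_times],
        "protocol": result.protocol.to_dict(),
        "config": result.config.to_dict(),
        "variant": result.params.name,
        "stim_start": result.protocol.t_start,
        "stim_end": result.protocol.t_stop,
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return csv_path, json_path
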