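"""Model-agnostic validation: capability contract, reference data, RMSE suites.

Any model implementation can be scored against reference data if it
satisfies a small somatic current-clamp capability: arm a square current
stimulus, run and record the somatic membrane potential, and reset to
the initial state.  Tests communicate with models only through this
contract, so the same suite can compare this package's own simulator, a
re-parameterized copy, or an external implementation wrapped in an
adapter.

Scores are root-mean-squared errors between the candidate's
feature-versus-current curve and the reference curve, in the feature's
own units.  Feature values are rounded to two decimals before scoring;
grid points where the feature is undefined on either side are excluded
pairwise rather than scored as agreement.

A full suite report is a tidy table of (variant, feature, RMSE,
n_points) rows — the machine twin of a published cross-implementation
comparison table, where a correct re-implementation shows an all-zero
column against its own reference.
"""

from __future__ import annotations

import abc
import csv
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as ft
from .model import (
    ModelParameters,
    SimulationConfig,
    StimulusProtocol,
    simulate,
    variant_parameters,
)

__all__ = [
    "ModelAdapter",
    "ReferenceSimulatorAdapter",
    "ProtocolTemplate",
    "FeatureTask",
    "Observation",
    "ReferenceSet",
    "ValidationReport",
    "AdapterContractError",
    "GridMismatchError",
    "SchemaError",
    "rmse",
    "run_feature_test",
    "run_suite",
    "make_reference",
    "level1_suite",
    "level2_suite",
    "load_reference",
    "save_reference",
    "DEPOL_TEMPLATE",
    "IV_TEMPLATE",
    "LEVEL2_SPIKE_GRIDS",
    "LEVEL2_IV_GRID",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


class AdapterContractError(RuntimeError):
    """The adapter violated the capability contract (e.g. reset is not
    reproducible)."""


class GridMismatchError(ValueError):
    """The reference stimulus grid is not a subset of the requested grid."""


class SchemaError(ValueError):
    """Reference file has an unexpected schema version or units."""


@dataclass(frozen=True)
class ProtocolTemplate:
    """Stimulus timing shared by every current of a test; the amplitude
    is filled in per grid point."""

    t_start: float
    t_stop: float
    t_total: float

    def with_amplitude(self, amplitude: float) -> StimulusProtocol:
        return StimulusProtocol(amplitude=amplitude, t_start=self.t_start,
                                t_stop=self.t_stop, t_total=self.t_total)


#: depolarizing battery: 1,000 ms pulse from t = 0
DEPOL_TEMPLATE = ProtocolTemplate(0.0, 1000.0, 1000.0)
#: passive battery: onset 1,500 ms, offset 4,000 ms, total 5,000 ms
IV_TEMPLATE = ProtocolTemplate(1500.0, 4000.0, 5000.0)


class ModelAdapter(abc.ABC):
    """Somatic current-clamp capability any candidate model must satisfy.

    Contract: after :meth:`reset_model`, an identical stimulate-and-run
    sequence must return identical output (no state leaks across runs).
    """

    @abc.abstractmethod
    def reset_model(self) -> None:
        """Restore the model to its initial state."""

    @abc.abstractmethod
    def inject_soma_square_current(self, protocol: StimulusProtocol) -> None:
        """Arm a square current stimulus for the next run."""

    @abc.abstractmethod
    def get_soma_vm(self, t_stop: float) -> ft.FeatureInput:
        """Run to ``t_stop`` and return the recorded somatic trace."""

    def run_stim_get_vm(self, t_stop: float,
                        protocol: StimulusProtocol) -> ft.FeatureInput:
        """Reset, arm the stimulus, run, and return the trace bundle."""
        self.reset_model()
        self.inject_soma_square_current(protocol)
        return self.get_soma_vm(t_stop)


class ReferenceSimulatorAdapter(ModelAdapter):
    """The built-in forward-Euler simulator wrapped in the capability
    contract.  This is the package's reference implementation; perturbed
    copies (different parameters, coarser dt) make useful candidates for
    exercising the suite."""

    def __init__(self, params: ModelParameters | str,
                 config: SimulationConfig | None = None):
        self.params = (variant_parameters(params)
                       if isinstance(params, str) else params)
        self.config = config or SimulationConfig()
        self._protocol: StimulusProtocol | None = None

    def reset_model(self) -> None:
        self._protocol = None

    def inject_soma_square_current(self, protocol: StimulusProtocol) -> None:
        self._protocol = protocol

    def get_soma_vm(self, t_stop: float) -> ft.FeatureInput:
        if self._protocol is None:
            raise AdapterContractError("no stimulus armed before get_soma_vm")
        proto = self._protocol
        if abs(t_stop - proto.t_total) > 1e-9:
            proto = replace(proto, t_total=t_stop)
        return simulate(self.params, proto, self.config).as_feature_input()


@dataclass(frozen=True)
class FeatureTask:
    """One (variant, feature, stimulus grid, protocol timing) test."""

    variant: str
    feature: str
    currents: tuple[float, ...]
    template: ProtocolTemplate


@dataclass(frozen=True)
class Observation:
    """Reference feature-versus-current data for one variant.

    ``values`` are pre-rounded to two decimals; ``None`` marks a grid
    point where the feature was undefined.
    """

    variant: str
    feature: str
    units: str
    currents: tuple[float, ...]
    values: tuple[float | None, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.currents) != len(self.values):
            raise ValueError("currents and values must be aligned")

    def value_array(self) -> np.ndarray:
        return np.array(
            [np.nan if v is None else v for v in self.values], dtype=float
        )


class ReferenceSet:
    """A collection of observations keyed by (variant, feature)."""

    def __init__(self, observations: Iterable[Observation] = ()):
        self._obs: dict[tuple[str, str], Observation] = {}
        for o in observations:
            self.add(o)

    def add(self, obs: Observation) -> None:
        expected = ft.FEATURE_UNITS.get(obs.feature)
        if expected is not None and obs.units != expected:
            raise SchemaError(
                f"units mismatch for {obs.feature!r}: file says {obs.units!r}, "
                f"expected {expected!r}"
            )
        self._obs[(obs.variant, obs.feature)] = obs

    def get(self, variant: str, feature: str) -> Observation | None:
        return self._obs.get((variant, feature))

    def __len__(self) -> int:
        return len(self._obs)

    def __iter__(self):
        return iter(self._obs.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferenceSet) and self._obs == other._obs


@dataclass
class ReportRow:
    variant: str
    feature: str
    candidate: str
    rmse: float | None
    n_points: int
    units: str
    error: str | None = None


@dataclass
class ValidationReport:
    """Per-variant, per-feature RMSE scores of a candidate model."""

    rows: list[ReportRow] = field(default_factory=list)

    @property
    def all_zero(self) -> bool:
        return bool(self.rows) and all(
            r.error is None and r.rmse == 0.0 for r in self.rows
        )

    @property
    def n_errors(self) -> int:
        return sum(1 for r in self.rows if r.error is not None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant": r.variant,
                    "feature": r.feature,
                    "candidate": r.candidate,
                    "rmse": None if r.rmse is None else ft.round2(r.rmse),
                    "n_points": r.n_points,
                    "units": r.units,
                    "error": r.error or "",
                }
                for r in self.rows
            ]
        )

    def pivot(self) -> pd.DataFrame:
        """Feature-by-variant grid of rounded RMSE values (the shape of a
        published cross-implementation comparison table)."""
        df = self.to_frame()
        return df.pivot_table(index="feature", columns="variant",
                              values="rmse", sort=False)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_markdown(self, path=None) -> str:
        df = self.to_frame()
        text = df.to_markdown(index=False)
        if path:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def rmse(predicted, reference) -> float:
    """Root mean squared error between two aligned value arrays.

    Pairs where either entry is NaN (the undefined-feature marker) are
    excluded before the computation; an empty result after exclusion is
    an error.  Full precision is returned; round for display only.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError(f"need equal-length 1-d arrays, got {p.shape} vs {r.shape}")
    keep = ~(np.isnan(p) | np.isnan(r))
    if not keep.any():
        raise ValueError("no defined value pairs left after pairwise exclusion")
    diff = p[keep] - r[keep]
    return float(np.sqrt(np.mean(diff * diff)))


def _predict(adapter: ModelAdapter, feature: str, currents: Sequence[float],
             template: ProtocolTemplate) -> np.ndarray:
    out = np.empty(len(currents))
    for i, amp in enumerate(currents):
        proto = template.with_amplitude(float(amp))
        fi = adapter.run_stim_get_vm(proto.t_total, proto)
        out[i] = ft.extract_feature_at(fi, feature, amplitude=float(amp))
    return out


def check_adapter_contract(adapter: ModelAdapter,
                           template: ProtocolTemplate = DEPOL_TEMPLATE,
                           amplitude: float = 0.0) -> None:
    """Verify reset reproducibility: two identical runs after reset must
    return bit-identical traces."""
    proto = template.with_amplitude(amplitude)
    a = adapter.run_stim_get_vm(proto.t_total, proto)
    b = adapter.run_stim_get_vm(proto.t_total, proto)
    if not (np.array_equal(a.vm, b.vm)
            and np.array_equal(a.spike_times, b.spike_times)):
        raise AdapterContractError(
            "adapter returned different output for identical runs after "
            "reset_model; state leaks across runs"
        )


def run_feature_test(
    adapter: ModelAdapter,
    feature: str,
    currents: Sequence[float],
    template: ProtocolTemplate,
    reference: Observation,
    candidate: str = "candidate",
    check_contract: bool = True,
) -> ReportRow:
    """Score one feature of one model against reference data.

    The reference grid must be a subset of the requested grid; the
    feature is evaluated on the reference grid (reset + stimulate per
    current), rounded, and scored with :func:`rmse`.
    """
    if feature not in ft.FEATURE_NAMES:
        raise KeyError(f"unknown feature {feature!r}")
    requested = {float(c) for c in currents}
    missing = [c for c in reference.currents if float(c) not in requested]
    if missing:
        raise GridMismatchError(
            f"reference currents {missing} absent from the requested grid"
        )
    if check_contract:
        check_adapter_contract(adapter, template,
                               amplitude=float(reference.currents[0]))
    pred = _predict(adapter, feature, reference.currents, template)
    ref = reference.value_array()
    keep = ~(np.isnan(pred) | np.isnan(ref))
    if not keep.any():
        raise ValueError(
            f"feature {feature!r} undefined at every grid point for both "
            "candidate and reference"
        )
    score = rmse(pred, ref)
    return ReportRow(
        variant=reference.variant, feature=feature, candidate=candidate,
        rmse=score, n_points=int(np.count_nonzero(keep)),
        units=reference.units,
    )


def run_suite(
    adapters: Mapping[str, ModelAdapter] | Callable[[str], ModelAdapter],
    suite: Sequence[FeatureTask],
    references: ReferenceSet,
    candidate: str = "candidate",
) -> ValidationReport:
    """Run every task of a suite, recording per-row failures without
    aborting the rest.

    ``adapters`` maps variant name to adapter (or is a factory callable).
    Each adapter's reset contract is checked once.
    """
    get = adapters if callable(adapters) else adapters.get
    report = ValidationReport()
    checked: set[int] = set()
    for task in suite:
        row = ReportRow(variant=task.variant, feature=task.feature,
                        candidate=candidate, rmse=None, n_points=0,
                        units=ft.FEATURE_UNITS.get(task.feature, ""))
        try:
            if task.feature not in ft.FEATURE_NAMES:
                raise KeyError(f"unknown feature {task.feature!r}")
            adapter = get(task.variant)
            if adapter is None:
                raise KeyError(f"no adapter for variant {task.variant!r}")
            if id(adapter) not in checked:
                check_adapter_contract(adapter, task.template,
                                       amplitude=float(task.currents[0]))
                checked.add(id(adapter))
            obs = references.get(task.variant, task.feature)
            if obs is None:
                raise KeyError(
                    f"no reference for ({task.variant}, {task.feature})"
                )
            scored = run_feature_test(
                adapter, task.feature, task.currents, task.template, obs,
                candidate=candidate, check_contract=False,
            )
            row.rmse, row.n_points, row.units = scored.rmse, scored.n_points, scored.units
        except Exception as exc:  # noqa: BLE001 - rows carry error states
            row.error = f"{type(exc).__name__}: {exc}"
        report.rows.append(row)
    return report


# --- suite definitions ------------------------------------------------------

_DEFAULT_VARIANTS = ("Pyr_Strong", "Pyr_Weak1", "Pyr_Weak2")

#: level-II spike-feature stimulus grids (pA); suprathreshold for every
#: variant so all spike features are defined
LEVEL2_SPIKE_GRIDS: Mapping[str, tuple[float, ...]] = {
    "Pyr_Strong": tuple(np.arange(100.0, 301.0, 50.0)),
    "Pyr_Weak1": tuple(np.arange(100.0, 351.0, 50.0)),
    "Pyr_Weak2": tuple(np.arange(100.0, 351.0, 50.0)),
}

#: level-II passive battery (pA)
LEVEL2_IV_GRID: tuple[float, ...] = (-10.0, -50.0, -100.0, -150.0, -200.0)

LEVEL2_SPIKE_FEATURES = (
    "spikecount",
    "time_to_first_spike", "time_to_second_spike", "time_to_last_spike",
    "AP1_amp", "AP2_amp", "APlast_amp",
    "AP1_width", "AP2_width", "APlast_width",
)


def _fi_grid(variant: str) -> tuple[float, ...]:
    from .characterize import default_fi_grid

    return tuple(default_fi_grid(variant_parameters(variant)))


def level1_suite(variants: Sequence[str] = _DEFAULT_VARIANTS) -> list[FeatureTask]:
    """Initial/final frequency tests over the default f-I grids."""
    return [
        FeatureTask(v, feat, _fi_grid(v), DEPOL_TEMPLATE)
        for v in variants
        for feat in ("initial_fi", "final_fi")
    ]


def level2_suite(variants: Sequence[str] = _DEFAULT_VARIANTS) -> list[FeatureTask]:
    """Spike-shape, spike-timing, count and passive I-V tests."""
    tasks = [
        FeatureTask(v, feat, LEVEL2_SPIKE_GRIDS[v], DEPOL_TEMPLATE)
        for v in variants
        for feat in LEVEL2_SPIKE_FEATURES
    ]
    tasks += [FeatureTask(v, "iv_curve", LEVEL2_IV_GRID, IV_TEMPLATE)
              for v in variants]
    return tasks


def make_reference(
    suite: Sequence[FeatureTask],
    adapters: Mapping[str, ModelAdapter] | None = None,
    provenance: str = "built-in reference simulator",
) -> ReferenceSet:
    """Generate reference observations by running a suite's tasks on the
    built-in simulator (or on the supplied adapters)."""
    refs = ReferenceSet()
    cache: dict[str, ModelAdapter] = {}

    def get(variant: str) -> ModelAdapter:
        if adapters is not None:
            return adapters[variant]
        if variant not in cache:
            cache[variant] = ReferenceSimulatorAdapter(variant)
        return cache[variant]

    for task in suite:
        pred = _predict(get(task.variant), task.feature, task.currents,
                        task.template)
        values = tuple(None if math.isnan(v) else float(v) for v in pred)
        refs.add(Observation(
            variant=task.variant, feature=task.feature,
            units=ft.FEATURE_UNITS.get(task.feature, ""),
            currents=tuple(float(c) for c in task.currents),
            values=values, provenance=provenance,
        ))
    return refs


# --- reference-data serialization ------------------------------------------

def save_reference(refs: ReferenceSet, path) -> None:
    """Write reference observations to JSON or tidy CSV (by extension)."""
    path = str(path)
    obs = sorted(refs, key=lambda o: (o.variant, o.feature))
    if path.endswith(".csv"):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["schema_version", "variant", "feature", "units",
                        "current_pA", "value", "provenance"])
            for o in obs:
                for c, v in zip(o.currents, o.values):
                    w.writerow([SCHEMA_VERSION, o.variant, o.feature, o.units,
                                repr(c), "" if v is None else repr(v),
                                o.provenance])
    else:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "observations": [
                {
                    "variant": o.variant,
                    "feature": o.feature,
                    "units": o.units,
                    "grid_pA": list(o.currents),
                    "values": list(o.values),
                    "provenance": o.provenance,
                }
                for o in obs
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def load_reference(path) -> ReferenceSet:
    """Read reference observations written by :func:`save_reference`."""
    path = str(path)
    refs = ReferenceSet()
    if path.endswith(".csv"):
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise SchemaError(f"empty reference file {path}")
        groups: dict[tuple[str, str], list[dict]] = {}
        for row in rows:
            if int(row["schema_version"]) != SCHEMA_VERSION:
                raise SchemaError(
                    f"unsupported schema version {row['schema_version']} "
                    f"(expected {SCHEMA_VERSION})"
                )
            groups.setdefault((row["variant"], row["feature"]), []).append(row)
        for (variant, feature), grp in groups.items():
            refs.add(Observation(
                variant=variant, feature=feature, units=grp[0]["units"],
                currents=tuple(float(r["current_pA"]) for r in grp),
                values=tuple(
                    None if r["value"] == "" else float(r["value"]) for r in grp
                ),
                provenance=grp[0].get("provenance", ""),
            ))
    else:
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema version {payload.get('schema_version')} "
                f"(expected {SCHEMA_VERSION})"
            )
        for o in payload["observations"]:
            refs.add(Observation(
                variant=o["variant"], feature=o["feature"], units=o["units"],
                currents=tuple(float(c) for c in o["grid_pA"]),
                values=tuple(
                    None if v is None else float(v) for v in o["values"]
                ),
                provenance=o.get("provenance", ""),
            ))
    return refs
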