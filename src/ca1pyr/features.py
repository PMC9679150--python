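"""Electrophysiological feature extraction from stimulated voltage traces.

Implements the small set of trace features used to characterize and
validate the pyramidal-cell models: instantaneous spiking frequencies
from the first and last inter-spike intervals, spike counts and
latencies, action-potential amplitude and half-width, and the
steady-state voltage deflection used for I-V curves.

Conventions shared by every feature:

* all extracted values are rounded to two decimal places
  (half-away-from-zero) before storage or comparison;
* a feature that cannot be computed on a given trace (e.g. the second
  spike's latency when only one spike fired) yields the undefined marker
  ``UNDEFINED`` (NaN), not an exception, so validation suites can
  exclude it pairwise;
* extraction never mutates its input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np

__all__ = [
    "FeatureInput",
    "FeatureVector",
    "UNDEFINED",
    "is_undefined",
    "round2",
    "spike_frequencies",
    "spike_count",
    "time_to_spike",
    "ap_amplitude",
    "ap_halfwidth",
    "voltage_deflection",
    "extract_feature",
    "FEATURE_NAMES",
    "FEATURE_UNITS",
    "ONSET_SLOPE_THRESHOLD",
]

#: marker for a feature that is undefined on a given trace
UNDEFINED = float("nan")

#: dV/dt threshold (mV/ms) marking the onset of an action potential
ONSET_SLOPE_THRESHOLD = 20.0


def is_undefined(x: float) -> bool:
    """True iff ``x`` is the undefined-feature marker."""
    return isinstance(x, float) and math.isnan(x)


def round2(x: float) -> float:
    """Round to two decimals, ties away from zero (so -0.005 -> -0.01)."""
    if is_undefined(x):
        return x
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class FeatureInput:
    """A stimulated trace bundled for feature extraction.

    Mirrors the (time, voltage, stim_start, stim_end) layout a
    trace-based feature library expects, plus the detected spike times.
    """

    times: np.ndarray
    vm: np.ndarray
    spike_times: np.ndarray
    stim_start: float
    stim_end: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.vm):
            raise ValueError("times and vm must be the same length")
        if not self.stim_start < self.stim_end:
            raise ValueError("need stim_start < stim_end")


class FeatureVector(dict):
    """Named feature values, each rounded to two decimals on insertion.

    A thin mapping ``feature name -> value`` (value may be the undefined
    marker).  Serializes to flat JSON (undefined -> null) and to tidy
    one-row-per-feature records.
    """

    def __setitem__(self, key: str, value: float) -> None:
        super().__setitem__(key, round2(value))

    def to_json_dict(self) -> dict:
        return {k: (None if is_undefined(v) else v) for k, v in self.items()}

    def to_records(self, variant: str, stimulus_pA: float) -> list[dict]:
        return [
            {
                "variant": variant,
                "stimulus_pA": stimulus_pA,
                "feature": k,
                "value": None if is_undefined(v) else v,
                "units": FEATURE_UNITS.get(k, ""),
            }
            for k, v in self.items()
        ]


def _check_sorted(spike_times: np.ndarray) -> np.ndarray:
    st = np.asarray(spike_times, dtype=float)
    if st.size > 1 and np.any(np.diff(st) < 0):
        raise ValueError("spike_times must be sorted ascending")
    return st


def spike_frequencies(spike_times) -> tuple[float, float]:
    """Initial and final instantaneous frequencies (Hz) from the ISIs.

    With two or more spikes these are the inverses of the first and last
    inter-spike intervals (1000/ISI_ms).  A single spike maps to
    (1, 1) Hz by convention; no spikes map to (0, 0) Hz.
    """
    st = _check_sorted(spike_times)
    if st.size == 0:
        return 0.0, 0.0
    if st.size == 1:
        return 1.0, 1.0
    return 1000.0 / (st[1] - st[0]), 1000.0 / (st[-1] - st[-2])


def spike_count(spike_times, window: tuple[float, float]) -> int:
    """Number of spikes with time in the half-open window [start, end)."""
    st = _check_sorted(spike_times)
    start, end = window
    return int(np.count_nonzero((st >= start) & (st < end)))


def time_to_spike(spike_times, stim_start: float, which: str) -> float:
    """Latency (ms) from stimulus onset to the first/second/last spike.

    Returns the undefined marker when the requested spike does not exist.
    """
    st = _check_sorted(spike_times)
    index = {"first": 0, "second": 1, "last": -1}
    if which not in index:
        raise ValueError(f"which must be one of {sorted(index)}, got {which!r}")
    i = index[which]
    needed = 2 if which == "second" else 1
    if st.size < needed:
        return UNDEFINED
    return float(st[i] - stim_start)


def _spike_onset_index(fi: FeatureInput, spike_index: int,
                       onset_slope: float) -> int | None:
    """Sample index where dV/dt first exceeds the onset slope rising into
    spike ``spike_index``, searching from the previous spike's reset (or
    the trace start).  None if no such sample exists."""
    st = fi.spike_times
    dt = float(fi.times[1] - fi.times[0])
    idx = int(round(st[spike_index] / dt))
    lo = int(round(st[spike_index - 1] / dt)) + 1 if spike_index > 0 else 0
    seg = fi.vm[lo:idx + 1]
    if seg.size < 2:
        return None
    slopes = np.diff(seg) / dt
    hits = np.flatnonzero(slopes >= onset_slope)
    if hits.size == 0:
        return None
    return lo + int(hits[0])


def _spike_window_end(fi: FeatureInput, spike_index: int,
                      onset_slope: float) -> int:
    """Last sample (exclusive) of this spike's search window: the next
    spike's onset if there is one, else the end of the trace."""
    if spike_index + 1 < fi.spike_times.size:
        nxt = _spike_onset_index(fi, spike_index + 1, onset_slope)
        if nxt is not None:
            return nxt + 1
        dt = float(fi.times[1] - fi.times[0])
        return int(round(fi.spike_times[spike_index + 1] / dt)) + 1
    return len(fi.vm)


def ap_amplitude(fi: FeatureInput, spike_index: int,
                 onset_slope: float = ONSET_SLOPE_THRESHOLD) -> float:
    """Action-potential amplitude (mV): peak voltage minus onset voltage.

    The onset is the sample where dV/dt first exceeds ``onset_slope``
    (mV/ms) rising into this spike; the peak is the trace maximum between
    that onset and the next spike's onset (or trace end).  Undefined if
    no onset is found.
    """
    st = fi.spike_times
    if not -st.size <= spike_index < st.size:
        raise IndexError(f"spike_index {spike_index} out of range for {st.size} spikes")
    spike_index = int(spike_index) % st.size
    j0 = _spike_onset_index(fi, spike_index, onset_slope)
    if j0 is None:
        return UNDEFINED
    j1 = _spike_window_end(fi, spike_index, onset_slope)
    peak = float(np.max(fi.vm[j0:j1]))
    return peak - float(fi.vm[j0])


def ap_halfwidth(fi: FeatureInput, spike_index: int,
                 onset_slope: float = ONSET_SLOPE_THRESHOLD) -> float:
    """Spike half-width (ms): time between the upward and downward
    crossings of the half-amplitude level (onset voltage + amplitude/2),
    located by linear interpolation between samples.  Undefined if the
    onset or either crossing cannot be found.
    """
    st = fi.spike_times
    if not -st.size <= spike_index < st.size:
        raise IndexError(f"spike_index {spike_index} out of range for {st.size} spikes")
    spike_index = int(spike_index) % st.size
    j0 = _spike_onset_index(fi, spike_index, onset_slope)
    if j0 is None:
        return UNDEFINED
    j1 = _spike_window_end(fi, spike_index, onset_slope)
    seg = fi.vm[j0:j1]
    t = fi.times[j0:j1]
    v_on = float(seg[0])
    peak_i = int(np.argmax(seg))
    half = v_on + (float(seg[peak_i]) - v_on) / 2.0

    up = None
    for j in range(peak_i):
        if seg[j] < half <= seg[j + 1]:
            frac = (half - seg[j]) / (seg[j + 1] - seg[j])
            up = t[j] + frac * (t[j + 1] - t[j])
            break
    down = None
    for j in range(peak_i, len(seg) - 1):
        if seg[j] >= half > seg[j + 1]:
            frac = (seg[j] - half) / (seg[j] - seg[j + 1])
            down = t[j] + frac * (t[j + 1] - t[j])
            break
    if up is None or down is None:
        return UNDEFINED
    return float(down - up)


def voltage_deflection(fi: FeatureInput) -> float:
    """Steady-state voltage deflection (mV) during a subthreshold step.

    Mean voltage over the last 10% of the stimulus window minus the mean
    over the last 100 ms before stimulus onset.  Requires at least 100 ms
    of pre-stimulus trace and the stimulus window to lie inside it.
    """
    t = fi.times
    if fi.stim_start < 100.0:
        raise ValueError(
            f"need >= 100 ms of pre-stimulus baseline, stimulus starts at "
            f"{fi.stim_start} ms"
        )
    if fi.stim_end > t[-1] + 1e-9:
        raise ValueError("stimulus window extends past the end of the trace")
    base = (t >= fi.stim_start - 100.0) & (t < fi.stim_start)
    tail_start = fi.stim_end - 0.1 * (fi.stim_end - fi.stim_start)
    tail = (t >= tail_start) & (t < fi.stim_end)
    if not base.any() or not tail.any():
        raise ValueError("baseline or steady-state window contains no samples")
    return float(fi.vm[tail].mean() - fi.vm[base].mean())


# --- named-feature dispatch -------------------------------------------------

FEATURE_UNITS: Mapping[str, str] = {
    "initial_fi": "Hz",
    "final_fi": "Hz",
    "spikecount": "count",
    "time_to_first_spike": "ms",
    "time_to_second_spike": "ms",
    "time_to_last_spike": "ms",
    "AP1_amp": "mV",
    "AP2_amp": "mV",
    "APlast_amp": "mV",
    "AP1_width": "ms",
    "AP2_width": "ms",
    "APlast_width": "ms",
    "iv_curve": "MΩ",
}

FEATURE_NAMES = tuple(FEATURE_UNITS)


def extract_feature(fi: FeatureInput, name: str) -> float:
    """Extract one named feature from a trace, rounded to two decimals.

    ``iv_curve`` is the per-stimulus point resistance: voltage deflection
    divided by the applied current, in MΩ (undefined at zero current);
    the applied current is inferred from nothing here, so it must be
    supplied via :func:`extract_feature_at` for that feature.
    """
    return extract_feature_at(fi, name, amplitude=None)


def extract_feature_at(fi: FeatureInput, name: str,
                       amplitude: float | None) -> float:
    """Like :func:`extract_feature` but with the stimulus amplitude (pA)
    available, as needed by the ``iv_curve`` point-resistance feature."""
    st = fi.spike_times
    if name == "initial_fi":
        value = spike_frequencies(st)[0]
    elif name == "final_fi":
        value = spike_frequencies(st)[1]
    elif name == "spikecount":
        value = spike_count(st, (float(fi.times[0]), float(fi.times[-1]) + 1e-9))
    elif name == "time_to_first_spike":
        value = time_to_spike(st, fi.stim_start, "first")
    elif name == "time_to_second_spike":
        value = time_to_spike(st, fi.stim_start, "second")
    elif name == "time_to_last_spike":
        value = time_to_spike(st, fi.stim_start, "last")
    elif name in ("AP1_amp", "AP2_amp", "APlast_amp"):
        idx = {"AP1_amp": 0, "AP2_amp": 1, "APlast_amp": -1}[name]
        needed = 2 if name == "AP2_amp" else 1
        value = ap_amplitude(fi, idx) if st.size >= needed else UNDEFINED
    elif name in ("AP1_width", "AP2_width", "APlast_width"):
        idx = {"AP1_width": 0, "AP2_width": 1, "APlast_width": -1}[name]
        needed = 2 if name == "AP2_width" else 1
        value = ap_halfwidth(fi, idx) if st.size >= needed else UNDEFINED
    elif name == "iv_curve":
        if amplitude is None or amplitude == 0:
            return UNDEFINED
        value = voltage_deflection(fi) / amplitude * 1000.0
    else:
        raise KeyError(
            f"unknown feature {name!r}; known features: {', '.join(FEATURE_NAMES)}"
        )
    return round2(value)
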