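"""Protocol batteries: f-I curves, rheobase search, I-V curves, input resistance.

All protocols are square current pulses simulated with forward Euler at
the default 0.02 ms step:

* f-I battery — 1,000 ms pulse from t = 0 per current; default grids
  -50..300 pA (strongly adapting) or -50..350 pA (weakly adapting) in
  10 pA steps; initial/final frequencies from the first/last ISI.
* rheobase — linear upward scan in 1 pA steps (spiking need not be
  monotone in current when the initial potential is depolarized, so no
  bisection); each candidate current is applied for 2,000 ms from t = 0,
  long enough to capture near-threshold spike latencies above 1 s.
* I-V battery — hyperpolarizing pulses with onset 1,500 ms, offset
  4,000 ms, total 5,000 ms, so a stable potential exists both before and
  at the end of the stimulus; deflection = steady-state minus baseline.
* input resistance — evaluated from the I-V curve under three
  conventions (see :func:`input_resistance`); the calibrated primary
  convention is the least-squares slope over currents -10..-30 pA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as ft
from .model import (
    ModelParameters,
    SimulationConfig,
    StimulusProtocol,
    simulate,
)

__all__ = [
    "FICurve",
    "IVCurve",
    "InputResistance",
    "RheobaseNotFoundError",
    "ProtocolError",
    "default_fi_grid",
    "fi_curve",
    "find_rheobase",
    "iv_curve",
    "input_resistance",
    "rebound_battery",
    "DEFAULT_IV_CURRENTS",
    "RHEOBASE_DURATION",
]

#: rheobase candidate pulse length (ms); near threshold the first spike
#: can lag stimulus onset by more than 1 s, so 1,000 ms is too short
RHEOBASE_DURATION = 2000.0

FI_DURATION = 1000.0

IV_ONSET, IV_OFFSET, IV_TOTAL = 1500.0, 4000.0, 5000.0

DEFAULT_IV_CURRENTS = tuple(-10.0 * i for i in range(41))  # 0 .. -400 pA


class RheobaseNotFoundError(RuntimeError):
    """No current in the scanned range elicited a spike."""


class ProtocolError(RuntimeError):
    """A protocol precondition was violated (e.g. spiking in a passive run)."""


@dataclass(frozen=True)
class FICurve:
    """Initial/final frequency versus injected current for one variant."""

    variant: str
    currents: np.ndarray
    f_initial: np.ndarray
    f_final: np.ndarray
    v_init: float
    duration: float

    def __post_init__(self) -> None:
        if not (len(self.currents) == len(self.f_initial) == len(self.f_final)):
            raise ValueError("currents, f_initial, f_final must be aligned")
        if np.any(np.diff(self.currents) <= 0):
            raise ValueError("currents must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "current_pA": self.currents,
                "f_initial_Hz": self.f_initial,
                "f_final_Hz": self.f_final,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        return {
            "variant": self.variant,
            "v_init": self.v_init,
            "duration": self.duration,
            "current_pA": list(map(float, self.currents)),
            "f_initial_Hz": list(map(float, self.f_initial)),
            "f_final_Hz": list(map(float, self.f_final)),
        }


@dataclass(frozen=True)
class IVCurve:
    """Steady-state voltage deflection versus hyperpolarizing current."""

    variant: str
    currents: np.ndarray
    deflections: np.ndarray

    def __post_init__(self) -> None:
        if len(self.currents) != len(self.deflections):
            raise ValueError("currents and deflections must be aligned")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"current_pA": self.currents, "deflection_mV": self.deflections}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        return {
            "variant": self.variant,
            "current_pA": list(map(float, self.currents)),
            "deflection_mV": list(map(float, self.deflections)),
        }


@dataclass(frozen=True)
class InputResistance:
    """Input resistance of one variant, under several conventions.

    ``value`` (MΩ) is the primary, calibrated convention: the
    least-squares slope of deflection against current over the currents
    in ``current_window`` (default -30..-10 pA).  Two alternative
    readings of the passive range are retained because the phrase
    "evaluated between -10 and -30" is ambiguous: the slope restricted
    to points whose *deflection* lies in ``deflection_window`` (mV), and
    the per-point ratio at the point nearest -10 mV deflection.
    ``ratio_table`` lists deflection/current (MΩ) for every battery
    point.
    """

    variant: str
    value: float
    convention: str
    n_points: int
    slope_current_window: float
    slope_deflection_window: float
    ratio_at_minus10mV: float
    ratio_table: pd.DataFrame


def default_fi_grid(params: ModelParameters) -> np.ndarray:
    """The default f-I current grid for a variant: -50..300 pA in 10 pA
    steps for the strongly adapting cell, -50..350 pA for the weakly
    adapting cells (classified by the recovery increment ``d``)."""
    top = 300.0 if params.d >= 10.0 else 350.0
    return np.arange(-50.0, top + 1e-9, 10.0)


def fi_curve(
    params: ModelParameters,
    currents: Sequence[float] | None = None,
    config: SimulationConfig | None = None,
    duration: float = FI_DURATION,
) -> FICurve:
    """Simulate a pulse per current and collect initial/final frequencies.

    Each pulse runs from t = 0 for ``duration`` ms.  Frequencies are
    rounded to two decimals.  Simulation failures are re-raised tagged
    with the offending current.
    """
    config = config or SimulationConfig()
    grid = np.asarray(currents if currents is not None else default_fi_grid(params),
                      dtype=float)
    if grid.size == 0:
        raise ValueError("currents must be non-empty")
    f_ini = np.empty(grid.size)
    f_fin = np.empty(grid.size)
    for i, amp in enumerate(grid):
        proto = StimulusProtocol(amplitude=float(amp), t_start=0.0,
                                 t_stop=duration, t_total=duration)
        try:
            res = simulate(params, proto, config)
        except Exception as exc:
            raise type(exc)(f"at current {amp} pA: {exc}") from exc
        ini, fin = ft.spike_frequencies(res.spike_times)
        f_ini[i] = ft.round2(ini)
        f_fin[i] = ft.round2(fin)
    return FICurve(variant=params.name, currents=grid, f_initial=f_ini,
                   f_final=f_fin, v_init=config.v_init, duration=duration)


def find_rheobase(
    params: ModelParameters,
    config: SimulationConfig | None = None,
    i_min: float = -60.0,
    i_max: float = 100.0,
    step: float = 1.0,
    duration: float = RHEOBASE_DURATION,
) -> float:
    """Smallest current on the grid {i_min, i_min+step, ...} eliciting a
    spike during a ``duration`` ms pulse from t = 0.

    The scan is a linear upward sweep: with a depolarized initial
    potential the spiking set need not be an upper half-line, so
    bisection is unsound.
    """
    if not (i_min < i_max):
        raise ValueError(f"need i_min < i_max, got [{i_min}, {i_max}]")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    config = config or SimulationConfig()
    n = int(np.floor((i_max - i_min) / step + 1e-9))
    for j in range(n + 1):
        amp = i_min + j * step
        proto = StimulusProtocol(amplitude=amp, t_start=0.0,
                                 t_stop=duration, t_total=duration)
        if simulate(params, proto, config).n_spikes >= 1:
            return amp
    raise RheobaseNotFoundError(
        f"no current in [{i_min}, {i_max}] pA (step {step}) elicited a spike "
        f"for {params.name}"
    )


def iv_curve(
    params: ModelParameters,
    currents: Sequence[float] | None = None,
    config: SimulationConfig | None = None,
) -> IVCurve:
    """Hyperpolarizing I-V battery: onset 1,500 ms, offset 4,000 ms,
    total 5,000 ms per current; deflection via the steady-state minus
    baseline rule, rounded to two decimals.

    All currents must be <= 0.  A spike at or before stimulus offset
    violates the passive-protocol assumption and raises
    :class:`ProtocolError` (rebound spikes after offset are tolerated:
    the excitable variants fire on release even from small steps).
    """
    config = config or SimulationConfig()
    grid = np.asarray(currents if currents is not None else DEFAULT_IV_CURRENTS,
                      dtype=float)
    if np.any(grid > 0):
        raise ProtocolError("I-V battery currents must be hyperpolarizing (<= 0)")
    defl = np.empty(grid.size)
    for i, amp in enumerate(grid):
        proto = StimulusProtocol(amplitude=float(amp), t_start=IV_ONSET,
                                 t_stop=IV_OFFSET, t_total=IV_TOTAL)
        res = simulate(params, proto, config)
        early = res.spike_times[res.spike_times <= IV_OFFSET]
        if early.size:
            raise ProtocolError(
                f"{params.name} spiked at {early[0]} ms during the passive "
                f"I-V protocol at {amp} pA"
            )
        defl[i] = ft.round2(ft.voltage_deflection(res.as_feature_input()))
    return IVCurve(variant=params.name, currents=grid, deflections=defl)


def input_resistance(
    iv: IVCurve,
    deflection_window: tuple[float, float] = (-30.0, -10.0),
    current_window: tuple[float, float] = (-30.0, -10.0),
    convention: str = "current_window",
) -> InputResistance:
    """Input resistance (MΩ) from an I-V battery.

    Conventions (all computed; ``convention`` selects ``value``):

    ``current_window``
        Least-squares slope of deflection vs current over battery points
        with current in ``current_window`` pA.  This is the calibrated
        primary convention: it reproduces the published values for all
        three built-in variants simultaneously.
    ``deflection_window``
        Least-squares slope over points whose deflection lies in
        ``deflection_window`` mV.
    ``ratio``
        Point ratio deflection/current at the battery point whose
        deflection is nearest -10 mV.

    Raises ``ValueError`` when the selected convention's window holds
    fewer than two points (the battery needs widening); windows the
    other conventions cannot fill are reported as NaN.
    """
    cur = np.asarray(iv.currents, dtype=float)
    defl = np.asarray(iv.deflections, dtype=float)

    def _slope(mask: np.ndarray, what: str, required: bool) -> float:
        if np.count_nonzero(mask) < 2:
            if required:
                raise ValueError(
                    f"fewer than 2 I-V points with {what}; widen the current battery"
                )
            return float("nan")
        return float(np.polyfit(cur[mask], defl[mask], 1)[0] * 1000.0)

    lo_c, hi_c = min(current_window), max(current_window)
    slope_cur = _slope((cur >= lo_c) & (cur <= hi_c),
                       f"current in [{lo_c}, {hi_c}] pA",
                       convention == "current_window")
    lo_d, hi_d = min(deflection_window), max(deflection_window)
    slope_defl = _slope((defl >= lo_d) & (defl <= hi_d),
                        f"deflection in [{lo_d}, {hi_d}] mV",
                        convention == "deflection_window")

    nz = cur != 0
    ratios = np.full(cur.size, np.nan)
    ratios[nz] = defl[nz] / cur[nz] * 1000.0
    near10 = int(np.argmin(np.abs(defl - (-10.0))))
    ratio10 = float(ratios[near10]) if cur[near10] != 0 else float("nan")

    table = pd.DataFrame(
        {"current_pA": cur, "deflection_mV": defl, "resistance_MOhm": ratios}
    )
    values = {
        "current_window": slope_cur,
        "deflection_window": slope_defl,
        "ratio": ratio10,
    }
    if convention not in values:
        raise ValueError(
            f"unknown convention {convention!r}; choose from {sorted(values)}"
        )
    mask = {
        "current_window": (cur >= lo_c) & (cur <= hi_c),
        "deflection_window": (defl >= lo_d) & (defl <= hi_d),
        "ratio": np.arange(cur.size) == near10,
    }[convention]
    return InputResistance(
        variant=iv.variant,
        value=values[convention],
        convention=convention,
        n_points=int(np.count_nonzero(mask)),
        slope_current_window=slope_cur,
        slope_deflection_window=slope_defl,
        ratio_at_minus10mV=ratio10,
        ratio_table=table,
    )


def rebound_battery(
    params: ModelParameters,
    amplitude: float,
    config: SimulationConfig | None = None,
    pulse: float = 1000.0,
    total: float = 2000.0,
):
    """Hyperpolarizing pulse with a stimulus-free tail, for rebound tests.

    Returns the simulation result; spikes after ``pulse`` are rebound
    spikes elicited by release from hyperpolarization.
    """
    if amplitude > 0:
        raise ProtocolError("rebound battery expects a hyperpolarizing amplitude")
    proto = StimulusProtocol(amplitude=amplitude, t_start=0.0,
                             t_stop=pulse, t_total=total)
    return simulate(params, proto, config or SimulationConfig())


# --- optional figure rendering ---------------------------------------------

def plot_fi(curves: Sequence[FICurve], path=None):
    """Render initial/final f-I curves (one panel pair) to ``path`` or show."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax_i, ax_f) = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for c in curves:
        ax_i.plot(c.currents, c.f_initial, marker=".", label=c.variant)
        ax_f.plot(c.currents, c.f_final, marker=".", label=c.variant)
    ax_i.set_title("initial frequency")
    ax_f.set_title("final frequency")
    for ax in (ax_i, ax_f):
        ax.set_xlabel("current (pA)")
        ax.set_ylabel("frequency (Hz)")
    ax_i.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_iv(curves: Sequence[IVCurve], path=None):
    """Render I-V curves to ``path`` or show."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for c in curves:
        ax.plot(c.currents, c.deflections, marker=".", label=c.variant)
    ax.set_xlabel("current (pA)")
    ax.set_ylabel("voltage deflection (mV)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
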