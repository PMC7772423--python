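"""Passive membrane properties from the 45 ms, -90 to -70 mV step.

Membrane capacitance is the charge of the capacitive transient divided by
the voltage step: the current is integrated (trapezoid, on the sampled grid)
from step onset to step end using the steady-state current at -70 mV as a
baseline, Cm = dQ/dV.  Membrane resistance is dV over the net steady current
increase relative to the -90 mV holding current; conductance is its
reciprocal.  Series resistance biases both estimates (Cm by a factor
(Rm/(Rm+Rs))^2, Rm by +Rs) and is deliberately not corrected — the analysis
reproduces the recording-side convention, not the underlying circuit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import SweepRecording, segment_bounds

__all__ = [
    "PassiveEstimate",
    "ProtocolMismatchError",
    "estimate_capacitance",
    "estimate_resistance",
    "conductance_density",
    "holding_current_density",
    "passive_estimate",
]


class ProtocolMismatchError(ValueError):
    """The sweep's protocol lacks the expected hold/step structure."""


@dataclass
class PassiveEstimate:
    """Per-cell passive properties. cm pF, rm GOhm, g nS, densities per pF."""

    cm: float
    rm: float
    g: float
    g_density: float  # pS/pF
    holding_density: float  # pA/pF
    delta_q: float  # pC
    delta_v: float  # mV
    baseline_current: float  # pA
    warning: str | None = None


def _find_step(sweep: SweepRecording) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Locate (hold segment before the step, step segment) sample bounds."""
    segs = sweep.protocol.segments
    bounds = segment_bounds(sweep.protocol)
    for i in range(1, len(segs)):
        prev, cur = segs[i - 1], segs[i]
        if prev.kind == "hold" and cur.kind in ("step", "hold") and cur.v_start != prev.v_start:
            return i, bounds[i - 1], bounds[i]
    raise ProtocolMismatchError("no hold-to-step transition found in protocol")


def estimate_capacitance(
    sweep: SweepRecording, baseline_window_ms: float = 10.0
) -> tuple[float, float]:
    """Membrane capacitance (pF) and transient charge dQ (pC) from one sweep.

    Baseline is the mean current over the final ``baseline_window_ms`` of
    the step; dQ is the trapezoidal integral of (current - baseline) from
    step onset to step end; Cm = dQ/dV.  A non-positive dQ for a
    depolarising step is returned but flagged with a warning.
    """
    i_step, _, (lo, hi) = _find_step(sweep)
    segs = sweep.protocol.segments
    dv = segs[i_step].v_start - segs[i_step - 1].v_start
    fs = sweep.protocol.sampling_khz
    nbase = int(round(baseline_window_ms * fs))
    if hi - lo < nbase + int(round(5.0 * fs)):
        raise ProtocolMismatchError("step too short for baseline window + 5 ms settle")
    baseline = float(np.mean(sweep.current[hi - nbase:hi]))
    # the step onset instant is the last holding sample (the command changes
    # during the following interval), so integration starts at lo - 1: this
    # gives the transient's first sample full interior trapezoid weight
    start = max(lo - 1, 0)
    dq_pa_ms = np.trapezoid(sweep.current[start:hi] - baseline, dx=1.0 / fs)
    dq = dq_pa_ms / 1000.0  # pA*ms -> pC
    cm = dq / (dv / 1000.0)  # pC / V -> pF
    if cm <= 0:
        warnings.warn("non-positive transient charge; capacitance estimate flagged")
    return cm, dq


def estimate_resistance(
    sweep: SweepRecording,
    baseline_window_ms: float = 10.0,
    holding_window_ms: float = 10.0,
    resolution_floor_pa: float = 0.1,
) -> float:
    """Membrane resistance (GOhm): dV over the net steady current increase.

    I_end is the mean over the final ``baseline_window_ms`` of the step and
    I_hold the mean over the final ``holding_window_ms`` before step onset.
    Returns ``inf`` when the net current change is below the resolution
    floor.
    """
    i_step, (hlo, hhi), (lo, hi) = _find_step(sweep)
    segs = sweep.protocol.segments
    dv = segs[i_step].v_start - segs[i_step - 1].v_start
    fs = sweep.protocol.sampling_khz
    nbase = int(round(baseline_window_ms * fs))
    nhold = int(round(holding_window_ms * fs))
    i_end = float(np.mean(sweep.current[hi - nbase:hi]))
    i_hold = float(np.mean(sweep.current[max(hlo, hhi - nhold):hhi]))
    di = i_end - i_hold
    if abs(di) < resolution_floor_pa:
        return float("inf")
    return dv / di  # mV / pA = GOhm


def conductance_density(cm: float, rm: float) -> float:
    """Leak conductance density in pS/pF from cm (pF) and rm (GOhm)."""
    return (1.0 / rm) / cm * 1000.0  # nS/pF -> pS/pF


def holding_current_density(
    sweep: SweepRecording, cm: float, holding_window_ms: float = 10.0
) -> float:
    """Mean holding current at the pre-step potential, normalised (pA/pF)."""
    _, (hlo, hhi), _ = _find_step(sweep)
    fs = sweep.protocol.sampling_khz
    nhold = int(round(holding_window_ms * fs))
    if hhi - hlo < nhold:
        raise ProtocolMismatchError("holding segment shorter than holding window")
    return float(np.mean(sweep.current[hhi - nhold:hhi])) / cm


def passive_estimate(sweep: SweepRecording, baseline_window_ms: float = 10.0) -> PassiveEstimate:
    """Full PassiveEstimate for one capacitance-protocol sweep."""
    cm, dq = estimate_capacitance(sweep, baseline_window_ms)
    rm = estimate_resistance(sweep, baseline_window_ms)
    i_step, _, (lo, hi) = _find_step(sweep)
    segs = sweep.protocol.segments
    dv = segs[i_step].v_start - segs[i_step - 1].v_start
    fs = sweep.protocol.sampling_khz
    nbase = int(round(baseline_window_ms * fs))
    baseline = float(np.mean(sweep.current[hi - nbase:hi]))
    g = 1.0 / rm if np.isfinite(rm) else 0.0
    warn = None
    if cm <= 0:
        warn = "non-positive transient charge"
    return PassiveEstimate(
        cm=cm,
        rm=rm,
        g=g,
        g_density=conductance_density(cm, rm) if cm > 0 and np.isfinite(rm) else float("nan"),
        holding_density=holding_current_density(sweep, cm) if cm > 0 else float("nan"),
        delta_q=dq,
        delta_v=dv,
        baseline_current=baseline,
        warning=warn,
    )
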