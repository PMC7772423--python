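"""Steady-state and tail-current analysis with Boltzmann activation fits.

Outward K+ currents are activated by 2 s voltage steps (-70..+70 mV) and
measured two ways: the steady-state current averaged over the last 200 ms
of the step, and the tail current upon repolarisation to -50 mV.  Tail
amplitudes are averaged over a 20 ms window centred at the tail peak; the
peak latency is located once on the +30 mV sweep and then applied at the
same latency to every activating voltage of the cell (the slow Kv12-like
tails peak there in most cells).  Fractional activation

    FA(V) = (I(V) - I(-70)) / (Imax - I(-70))

uses raw (not leak-subtracted) tail values — any leak contribution is part
of I(-70) and cancels by construction.  FA(V) is proportional to the
fractional activation of conductance and is fitted with the Boltzmann
sigmoid 1 / (1 + exp(-(V - V0.5)/S)), where V0.5 is the half-activation
voltage and S the inverse slope factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

from .simulate import SweepRecording, segment_bounds

__all__ = [
    "ActivationCurve",
    "BoltzmannFit",
    "steady_state_current",
    "tail_peak_latency",
    "tail_amplitude",
    "activation_curve",
    "fractional_activation",
    "boltzmann_eval",
    "fit_boltzmann",
]


@dataclass
class ActivationCurve:
    """Tail amplitudes vs activating voltage for one cell (pA/pF)."""

    activating_v: np.ndarray
    tail_amp: np.ndarray
    i_minus70: float
    i_max: float
    fa: np.ndarray | None = None
    latency_ms: float | None = None
    latency_fallback: bool = False


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann parameters: V0.5 (mV), inverse slope S (mV)."""

    v_half: float
    slope_s: float
    amplitude: float
    rss: float
    converged: bool


def _activating_and_tail(sweep: SweepRecording):
    """Bounds of the activating step and the following tail segment."""
    segs = sweep.protocol.segments
    bounds = segment_bounds(sweep.protocol)
    if len(segs) < 2:
        raise ValueError("protocol has no activating step + tail structure")
    return segs[-2], bounds[-2], segs[-1], bounds[-1]


def steady_state_current(sweep: SweepRecording, cm: float, window_ms: float = 200.0) -> float:
    """Mean current over the final ``window_ms`` of the activating step, pA/pF."""
    act_seg, (lo, hi), _, _ = _activating_and_tail(sweep)
    fs = sweep.protocol.sampling_khz
    n = int(round(window_ms * fs))
    if hi - lo < n:
        raise ValueError("activating step shorter than the averaging window")
    return float(np.mean(sweep.current[hi - n:hi])) / cm


def tail_peak_latency(
    sweep: SweepRecording,
    smooth_points: int = 5,
    search_ms: float = 500.0,
    late_baseline_ms: float = 100.0,
    blank_ms: float = 20.0,
) -> float:
    """Latency (ms from tail onset) of the tail-current peak.

    The peak is the extremum of largest magnitude relative to the late-tail
    baseline, on a median-smoothed trace, within the first ``search_ms`` of
    the tail — polarity-agnostic, since tails at -50 mV are outward for K+
    (EK ~ -85 mV) but the same machinery serves either sign.  The first
    ``blank_ms`` of the tail are excluded from the search: the capacitive
    transient of the repolarisation (stretched by the acquisition filter)
    would otherwise masquerade as the channel tail peak.
    """
    _, _, _, (lo, hi) = _activating_and_tail(sweep)
    fs = sweep.protocol.sampling_khz
    tail = sweep.current[lo:hi]
    if smooth_points > 1:
        tail = median_filter(tail, size=smooth_points, mode="nearest")
    nblank = min(int(round(blank_ms * fs)), len(tail) - 1)
    nsearch = min(int(round(search_ms * fs)), len(tail))
    nlate = max(int(round(late_baseline_ms * fs)), 1)
    late = float(np.mean(tail[-nlate:]))
    k = nblank + int(np.argmax(np.abs(tail[nblank:nsearch] - late)))
    return k / fs


def tail_amplitude(
    sweep: SweepRecording,
    cm: float,
    latency_ms: float | None = None,
    window_ms: float = 20.0,
    subtract_baseline: bool = False,
    late_baseline_ms: float = 100.0,
) -> float:
    """Mean tail current over a ``window_ms`` window centred at the peak.

    Raw value by default (baseline not subtracted — fractional activation
    uses the -70 mV tail as its reference, so shared leak cancels there),
    normalised by cm.  ``subtract_baseline`` removes the late-tail mean
    instead, isolating the decaying channel component — the measure used
    for drug-sequence ratios, where a fully blocked cell must read zero.
    When ``latency_ms`` is given the window is centred at that fixed
    latency; otherwise the peak is located on this sweep.
    """
    if latency_ms is None:
        latency_ms = tail_peak_latency(sweep)
    _, _, _, (lo, hi) = _activating_and_tail(sweep)
    fs = sweep.protocol.sampling_khz
    center = lo + int(round(latency_ms * fs))
    half = int(round(window_ms * fs / 2.0))
    a = max(lo, center - half)
    b = min(hi, center + half + 1)
    if b <= a:
        raise ValueError("tail window empty")
    value = float(np.mean(sweep.current[a:b]))
    if subtract_baseline:
        nlate = max(int(round(late_baseline_ms * fs)), 1)
        value -= float(np.mean(sweep.current[hi - nlate:hi]))
    return value / cm


def activation_curve(
    battery: dict[float, SweepRecording],
    cm: float,
    reference_v: float = 30.0,
    window_ms: float = 20.0,
) -> ActivationCurve:
    """Per-cell tail amplitudes across activating voltages at fixed latency.

    The tail-peak latency is located on the ``reference_v`` (+30 mV) sweep
    and applied to every sweep of the battery; if that sweep is missing the
    latency falls back to the per-cell global tail peak (flagged).
    """
    voltages = np.array(sorted(battery))
    fallback = False
    if reference_v in battery:
        latency = tail_peak_latency(battery[reference_v])
    else:
        fallback = True
        best, latency = 0.0, 0.0
        for v in voltages:
            lat = tail_peak_latency(battery[v])
            amp = abs(tail_amplitude(battery[v], 1.0, lat, window_ms))
            if amp > best:
                best, latency = amp, lat
    amps = np.array([tail_amplitude(battery[v], cm, latency, window_ms) for v in voltages])
    if -70.0 not in battery:
        raise ValueError("battery must include the -70 mV activating step")
    i70 = float(amps[np.argmin(np.abs(voltages - (-70.0)))])
    return ActivationCurve(
        activating_v=voltages,
        tail_amp=amps,
        i_minus70=i70,
        i_max=float(np.max(amps)),
        latency_ms=latency,
        latency_fallback=fallback,
    )


def fractional_activation(curve: ActivationCurve) -> np.ndarray:
    """FA(V) = (I(V) - I(-70)) / (Imax - I(-70)); stored on the curve."""
    if curve.i_max == curve.i_minus70:
        raise ValueError("undefined activation: Imax equals I(-70)")
    fa = (curve.tail_amp - curve.i_minus70) / (curve.i_max - curve.i_minus70)
    curve.fa = fa
    return fa


def boltzmann_eval(v, v_half: float, slope_s: float):
    """Boltzmann sigmoid 1 / (1 + exp(-(v - v_half)/slope_s))."""
    if slope_s <= 0:
        raise ValueError("slope_s must be > 0")
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - v_half) / slope_s))


def fit_boltzmann(
    v, y, fix_amplitude: bool = True, slope_bounds: tuple[float, float] = (0.5, 100.0)
) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit.

    Amplitude is fixed to 1 for fractional-activation data and free for
    conductance data.  Initialisation: V0.5 at the abscissa whose y is
    closest to half-range, S = 10 mV.  Non-convergence returns the best
    iterate with ``converged=False``.
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 points to fit")
    if np.ptp(y) == 0:
        raise ValueError("all y values equal; Boltzmann fit undefined")
    half = (np.min(y) + np.max(y)) / 2.0
    v0 = float(v[np.argmin(np.abs(y - half))])
    converged = True
    try:
        if fix_amplitude:
            popt, _ = curve_fit(
                lambda vv, vh, s: boltzmann_eval(vv, vh, s),
                v, y, p0=[v0, 10.0],
                bounds=([-np.inf, slope_bounds[0]], [np.inf, slope_bounds[1]]),
                maxfev=10000,
            )
            vh, s = popt
            amp = 1.0
        else:
            popt, _ = curve_fit(
                lambda vv, a, vh, s: a * boltzmann_eval(vv, vh, s),
                v, y, p0=[float(np.max(y)), v0, 10.0],
                bounds=([-np.inf, -np.inf, slope_bounds[0]], [np.inf, np.inf, slope_bounds[1]]),
                maxfev=10000,
            )
            amp, vh, s = popt
    except RuntimeError:
        converged = False
        amp, vh, s = (1.0 if fix_amplitude else float(np.max(y))), v0, 10.0
    resid = y - amp * boltzmann_eval(v, vh, s)
    return BoltzmannFit(
        v_half=float(vh), slope_s=float(s), amplitude=float(amp),
        rss=float(np.sum(resid**2)), converged=converged,
    )
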