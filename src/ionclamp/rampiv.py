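"""Net inward current through Ca2+ channels from voltage-ramp sweeps.

The ramp current is dominated by a linear leak plus, where Ca2+ channels
are present, an inward deflection peaking close to +10 mV.  The leak is fit
as a straight line over a sub-threshold voltage window (default -90 to
-40 mV, below the activation range of every modelled conductance) and
extrapolated; the net inward current is the most negative residual within
the search window, normalised to membrane capacitance when available.
Commanded (not measured) voltage is the abscissa: series-resistance errors
are part of the recording being analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .simulate import SweepRecording, command_waveform, segment_bounds

__all__ = ["RampIV", "average_ramp_sweeps", "fit_leak_line", "net_inward_current", "ramp_axes"]


@dataclass
class RampIV:
    """Leak-subtracted ramp I-V summary for one cell/solution."""

    voltage: np.ndarray  # mV
    current: np.ndarray  # pA (or pA/pF when normalised)
    leak_slope: float  # nS (or nS/pF)
    leak_intercept: float  # pA at 0 mV
    peak_voltage: float  # mV
    net_peak: float  # signed, inward negative
    fit_range: tuple[float, float]
    no_deflection: bool = False


def ramp_axes(sweep: SweepRecording) -> tuple[np.ndarray, np.ndarray]:
    """(commanded voltage, current) restricted to the ramp segment."""
    bounds = segment_bounds(sweep.protocol)
    for (lo, hi), seg in zip(bounds, sweep.protocol.segments):
        if seg.kind == "ramp":
            vc = command_waveform(sweep.protocol)[lo:hi]
            return vc, sweep.current[lo:hi]
    raise ValueError("no ramp segment in protocol")


def average_ramp_sweeps(sweeps: list[SweepRecording]) -> SweepRecording:
    """Pointwise mean of repeated sweeps sharing one protocol."""
    if not sweeps:
        raise ValueError("no sweeps to average")
    first = sweeps[0]
    for s in sweeps[1:]:
        if s.protocol != first.protocol or len(s.current) != len(first.current):
            raise ValueError("sweeps must share protocol and length")
    mean = np.mean([s.current for s in sweeps], axis=0)
    out = SweepRecording(
        time=first.time.copy(), current=mean, protocol=first.protocol,
        solution=first.solution, drug=first.drug, cell_id=first.cell_id,
        genotype=first.genotype, day=first.day, cm_pf=first.cm_pf,
    )
    return out


def fit_leak_line(
    sweep: SweepRecording,
    fit_range: tuple[float, float] = (-90.0, -40.0),
    settle_ms: float = 5.0,
) -> tuple[float, float]:
    """OLS line (slope nS, intercept pA at 0 mV) of current vs command voltage.

    The first ``settle_ms`` of the ramp are excluded: the acquisition
    filter's warm-up at ramp onset would otherwise act as high-leverage
    outliers on the extrapolated line.
    """
    v, i = ramp_axes(sweep)
    lo, hi = fit_range
    mask = (v >= lo) & (v <= hi)
    n_settle = int(round(settle_ms * sweep.protocol.sampling_khz))
    mask[:n_settle] = False
    if mask.sum() < 20:
        raise ValueError("fit_range contains fewer than 20 samples")
    slope, intercept = np.polyfit(v[mask], i[mask], 1)
    return float(slope), float(intercept)


def net_inward_current(
    sweep: SweepRecording,
    leak_fit: tuple[float, float] | None = None,
    search_range: tuple[float, float] = (-30.0, 40.0),
    fit_range: tuple[float, float] = (-90.0, -40.0),
    smooth_points: int = 5,
    normalize: bool = True,
    resolution_pa: float = 1.0,
) -> RampIV:
    """Peak leak-subtracted inward current on the ramp.

    The residual (current minus the leak line) is median-smoothed over
    ``smooth_points`` samples; the peak is its minimum within
    ``search_range``.  When no residual below ``-resolution_pa`` exists
    (leak-line extrapolation error sets the resolution floor) the result is
    0 with the ``no_deflection`` flag set.
    """
    if leak_fit is None:
        leak_fit = fit_leak_line(sweep, fit_range)
    slope, intercept = leak_fit
    v, i = ramp_axes(sweep)
    residual = i - (slope * v + intercept)
    if smooth_points > 1:
        residual = median_filter(residual, size=smooth_points, mode="nearest")
    mask = (v >= search_range[0]) & (v <= search_range[1])
    if not mask.any():
        raise ValueError("search_range outside the ramp span")
    idx = np.flatnonzero(mask)
    k = idx[np.argmin(residual[idx])]
    net = float(residual[k])
    no_deflection = net >= -abs(resolution_pa)
    if no_deflection:
        net = 0.0
    cm = sweep.cm_pf if (normalize and sweep.cm_pf) else 1.0
    return RampIV(
        voltage=v,
        current=i / cm,
        leak_slope=slope / cm,
        leak_intercept=intercept / cm,
        peak_voltage=float(v[k]),
        net_peak=net / cm,
        fit_range=fit_range,
        no_deflection=no_deflection,
    )
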