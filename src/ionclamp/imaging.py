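"""dF/F0 quantification of Fluo-4 traces and the CTCF intensity statistic.

Fluorescence responses to a 30 mM KCl depolarisation window are normalised
to the pre-stimulus baseline F0 (mean of all pre-stimulus frames); dF/F0 is
the peak in-stimulus fluorescence relative to F0 — a gain-free proxy for
Ca2+ influx through voltage-gated channels.  Corrected total cell
fluorescence (CTCF) for immunofluorescence ROIs is
integrated density - ROI area * mean background gray value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import FluorescenceTrace

__all__ = ["CtcfInput", "baseline_f0", "delta_f_over_f0", "ctcf"]


@dataclass(frozen=True)
class CtcfInput:
    """Per-ROI intensity measurements for the CTCF statistic."""

    integrated_density: float  # a.u.
    roi_area: float  # pixel^2
    background_mean: float  # a.u. per pixel

    def __post_init__(self) -> None:
        if self.roi_area <= 0:
            raise ValueError("roi_area must be > 0")
        for name in ("integrated_density", "roi_area", "background_mean"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def baseline_f0(trace: FluorescenceTrace, min_frames: int = 3) -> float:
    """Mean fluorescence over all pre-stimulus frames."""
    pre = trace.f[np.asarray(trace.t) < trace.stim_window[0]]
    if len(pre) < min_frames:
        raise ValueError(f"need at least {min_frames} pre-stimulus frames")
    return float(np.mean(pre))


def delta_f_over_f0(
    trace: FluorescenceTrace, min_frames: int = 3, mode: str = "peak"
) -> float:
    """(peak F within the stimulus window - F0) / F0.

    ``mode='mean'`` uses the in-window mean instead of the peak.
    """
    f0 = baseline_f0(trace, min_frames)
    t = np.asarray(trace.t)
    mask = (t >= trace.stim_window[0]) & (t <= trace.stim_window[1])
    if not mask.any():
        raise ValueError("stimulus window contains no frames")
    stat = np.max if mode == "peak" else np.mean
    return float((stat(trace.f[mask]) - f0) / f0)


def ctcf(inp: CtcfInput) -> float:
    """Corrected total cell fluorescence (a.u.)."""
    return inp.integrated_density - inp.roi_area * inp.background_mean
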