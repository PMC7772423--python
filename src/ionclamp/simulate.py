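"""Conductance-based voltage-clamp simulator and synthetic-data generators.

The simulator stands in for perforated-patch recordings from differentiated
SH-SY5Y-like cells: a passive RC membrane accessed through a series
resistance, plus up to three gated conductance families —

* ``kv11``  — fast-deactivating voltage-gated K+ channels (KCNH / ERG-like),
  blocked by 4-AP;
* ``kv12``  — slowly-deactivating K+ channels (KCNH / ELK-like), potentiated
  by 4-AP and blocked by NS-1643;
* ``vgcc``  — voltage-gated Ca2+ channels, carrying larger currents when
  Ba2+ replaces Ca2+ as the charge carrier.

Each gated family has a single activation gate relaxing with first-order
kinetics toward a Boltzmann steady state (``tau_act`` when opening,
``tau_deact`` when closing); there is no inactivation.  The clamp circuit is
the standard two-node model::

    Cm dVm/dt = (Vc - Vm)/Rs - sum_f g_f m_f (Vm - E_f) - (Vm - E_leak)/Rm

with the recorded current ``(Vc - Vm)/Rs``.  Units are mV / ms / pA / pF /
GOhm / nS throughout (so I[pA] = V[mV] / R[GOhm] = g[nS] * V[mV]).

Besides sweeps, the module generates Fluo-4-like fluorescence traces in
response to a KCl depolarisation window and FPKM expression tables with
known fold-change truth, so every downstream analysis stage has a
parameter-recovery oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy import signal

__all__ = [
    "ChannelSpec",
    "SimCellParams",
    "ProtocolSpec",
    "Segment",
    "SweepRecording",
    "SimTruth",
    "FluorescenceTrace",
    "IntegrationError",
    "simulate_sweep",
    "simulate_population",
    "simulate_fluorescence_traces",
    "simulate_expression_table",
    "mock_default",
    "cln1_default",
    "default_population_config",
    "capacitance_protocol",
    "ramp_protocol",
    "tail_protocol",
    "command_waveform",
    "segment_bounds",
]

SOLUTIONS = ("tyrode_ca", "ba_tea", "kcl30")
DRUGS = ("none", "ap4", "ap4_ns1643")
FAMILIES = ("leak", "kv11", "kv12", "vgcc")

#: Nernst potential for K+ with 5 mM out / 140 mM in at room temperature.
E_K = -85.0


class IntegrationError(RuntimeError):
    """Raised when the clamp integration produces a non-finite state."""


@dataclass(frozen=True)
class ChannelSpec:
    """One conductance family of a synthetic cell.

    ``g_density`` is in pS/pF, reversal and gating voltages in mV, time
    constants in ms.  Drug fields describe instantaneous conductance
    rescaling: in 4-AP the family conductance becomes
    ``g * (1 - block_4ap) * potentiate_4ap`` and NS-1643 (applied on top of
    4-AP) multiplies by ``(1 - block_ns)``.  ``carrier_gain_ba`` is the
    conductance multiplier when Ba2+ replaces Ca2+ (vgcc only; ignored for
    other families).
    """

    family: str
    g_density: float
    e_rev: float
    v_half: float = 0.0
    slope: float = 10.0
    tau_act: float = 10.0
    tau_deact: float = 10.0
    block_4ap: float = 0.0
    potentiate_4ap: float = 1.0
    block_ns: float = 0.0
    carrier_gain_ba: float = 6.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown channel family {self.family!r}")
        if self.g_density < 0:
            raise ValueError("g_density must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError("time constants must be > 0")
        for name in ("block_4ap", "block_ns"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.potentiate_4ap < 1.0:
            raise ValueError("potentiate_4ap must be >= 1")
        if self.family == "vgcc" and self.carrier_gain_ba <= 0:
            raise ValueError("carrier_gain_ba must be > 0 for vgcc")

    def drug_scale(self, drug: str) -> float:
        """Multiplicative conductance scale for a drug condition."""
        if drug == "none":
            return 1.0
        if drug == "ap4":
            return (1.0 - self.block_4ap) * self.potentiate_4ap
        if drug == "ap4_ns1643":
            return (1.0 - self.block_4ap) * self.potentiate_4ap * (1.0 - self.block_ns)
        raise ValueError(f"unknown drug {drug!r}")

    def solution_scale(self, solution: str) -> float:
        """Multiplicative conductance scale for a bath solution."""
        if solution not in SOLUTIONS:
            raise ValueError(f"unknown solution {solution!r}")
        if solution == "ba_tea":
            # TEA blocks the Kv families; Ba2+ boosts vgcc permeation.
            if self.family in ("kv11", "kv12"):
                return 0.0
            if self.family == "vgcc":
                return self.carrier_gain_ba
        return 1.0


@dataclass(frozen=True)
class SimCellParams:
    """Generative parameters of one synthetic cell.

    cm in pF, rm in GOhm, rs in MOhm, e_leak in mV, noise_sd in pA
    (per-sample current noise added before filtering).
    """

    cm: float
    rm: float
    rs: float
    e_leak: float
    channels: tuple[ChannelSpec, ...] = ()
    genotype: str = "mock"
    day: int = 5
    noise_sd: float = 0.0
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("cm must be > 0")
        if self.rm <= 0:
            raise ValueError("rm must be > 0")
        if not 0.0 <= self.rs < 80.0:
            raise ValueError("rs must be in [0, 80) MOhm (recording acceptance rule)")
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.genotype not in ("mock", "cln1"):
            raise ValueError("genotype must be 'mock' or 'cln1'")
        object.__setattr__(self, "channels", tuple(self.channels))


@dataclass(frozen=True)
class Segment:
    """One protocol segment: hold, step, or linear ramp."""

    kind: str
    v_start: float
    v_end: float
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "step", "ramp"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.kind in ("hold", "step") and self.v_start != self.v_end:
            raise ValueError("hold/step segments need v_start == v_end")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered voltage-command segments plus acquisition settings."""

    segments: tuple[Segment, ...]
    sampling_khz: float
    filter_khz: float = 0.0  # 3-pole Bessel low-pass cutoff; 0 disables
    n_sweep_avg: int = 1
    name: str = "protocol"

    def __post_init__(self) -> None:
        if self.sampling_khz <= 0:
            raise ValueError("sampling_khz must be > 0")
        if self.n_sweep_avg < 1:
            raise ValueError("n_sweep_avg must be >= 1")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_khz

    def n_samples(self) -> int:
        return sum(int(round(s.duration * self.sampling_khz)) for s in self.segments)


@dataclass
class SweepRecording:
    """One recorded (or simulated) voltage-clamp sweep."""

    time: np.ndarray  # ms, uniform grid
    current: np.ndarray  # pA, inward negative
    protocol: ProtocolSpec
    solution: str = "tyrode_ca"
    drug: str = "none"
    cell_id: str = "cell"
    genotype: str = "mock"
    day: int = 5
    cm_pf: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(
                dt, 1.0 / self.protocol.sampling_khz, rtol=1e-6, atol=1e-9
            ):
                raise ValueError("time must increase with constant step 1/sampling_khz")
        if self.solution not in SOLUTIONS:
            raise ValueError(f"unknown solution {self.solution!r}")
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")


@dataclass
class SimTruth:
    """Ground truth for one synthetic cell (parameter-recovery oracle)."""

    params: SimCellParams
    cm: float
    g_leak_ns: float
    g_density: dict[str, float]  # per family, pS/pF
    v_half: dict[str, float]
    slope: dict[str, float]


@dataclass
class FluorescenceTrace:
    """Fluo-4-like ROI time series with generative truth amplitude."""

    t: np.ndarray  # s
    f: np.ndarray  # arbitrary units, > 0
    stim_window: tuple[float, float]  # s
    roi_id: str
    genotype: str
    day: int
    true_amplitude: float | None = None


# ---------------------------------------------------------------------------
# protocol builders (defaults follow the acquisition settings of the study)
# ---------------------------------------------------------------------------


def capacitance_protocol(
    hold_ms: float = 50.0, step_ms: float = 45.0, post_ms: float = 30.0
) -> ProtocolSpec:
    """45 ms, 20 mV step from -90 mV; 50 kHz sampling, 5 kHz Bessel, 64 sweeps."""
    return ProtocolSpec(
        segments=(
            Segment("hold", -90.0, -90.0, hold_ms),
            Segment("step", -70.0, -70.0, step_ms),
            Segment("hold", -90.0, -90.0, post_ms),
        ),
        sampling_khz=50.0,
        filter_khz=5.0,
        n_sweep_avg=64,
        name="capacitance",
    )


def ramp_protocol(hold_ms: float = 100.0, post_ms: float = 50.0) -> ProtocolSpec:
    """-90 to +80 mV in 270 ms; 5 kHz sampling, 1 kHz Bessel, 16 sweeps."""
    return ProtocolSpec(
        segments=(
            Segment("hold", -90.0, -90.0, hold_ms),
            Segment("ramp", -90.0, 80.0, 270.0),
            Segment("hold", -90.0, -90.0, post_ms),
        ),
        sampling_khz=5.0,
        filter_khz=1.0,
        n_sweep_avg=16,
        name="ramp",
    )


def tail_protocol(
    v_step: float,
    hold_ms: float = 200.0,
    step_ms: float = 2000.0,
    tail_ms: float = 1000.0,
) -> ProtocolSpec:
    """2 s activating step from -80 mV with a -50 mV tail; 1 kHz / 0.3 kHz."""
    return ProtocolSpec(
        segments=(
            Segment("hold", -80.0, -80.0, hold_ms),
            Segment("step", v_step, v_step, step_ms),
            Segment("step", -50.0, -50.0, tail_ms),
        ),
        sampling_khz=1.0,
        filter_khz=0.3,
        n_sweep_avg=1,
        name=f"tail_{v_step:+.0f}mV",
    )


#: Activating voltages of the tail battery, -70..+70 mV in 10 mV increments.
TAIL_VOLTAGES = tuple(float(v) for v in range(-70, 80, 10))


def command_waveform(protocol: ProtocolSpec) -> np.ndarray:
    """Per-sample command voltage (mV) for a protocol."""
    parts = []
    for seg in protocol.segments:
        n = int(round(seg.duration * protocol.sampling_khz))
        if seg.kind == "ramp":
            # exclusive of the end point so concatenated segments stay uniform
            parts.append(seg.v_start + (seg.v_end - seg.v_start) * np.arange(n) / n)
        else:
            parts.append(np.full(n, seg.v_start))
    return np.concatenate(parts)


def segment_bounds(protocol: ProtocolSpec) -> list[tuple[int, int]]:
    """[start, stop) sample indices for each protocol segment."""
    bounds = []
    start = 0
    for seg in protocol.segments:
        n = int(round(seg.duration * protocol.sampling_khz))
        bounds.append((start, start + n))
        start += n
    return bounds


# ---------------------------------------------------------------------------
# integration core
# ---------------------------------------------------------------------------


@njit(cache=True)
def _integrate_clamp(vc, dt, nsub, cm, g_leak, e_leak, rs_gohm,
                     g_ns, e_rev, v_half, slope, tau_act, tau_deact, gated):
    """Exponential-Euler integration of the two-node clamp circuit.

    Exact for the membrane equation with gates frozen over each substep;
    gate states use the analytic first-order update.  Returns the recorded
    pipette current (pA) sampled at the end of each command interval.
    """
    n = vc.shape[0]
    nch = g_ns.shape[0]
    i_rec = np.empty(n)
    dts = dt / nsub

    # steady-state initialisation at the first command voltage
    vm = vc[0]
    m = np.empty(nch)
    for _ in range(50):
        gtot = g_leak
        gsum_e = g_leak * e_leak
        for j in range(nch):
            if gated[j]:
                m[j] = 1.0 / (1.0 + math.exp(-(vm - v_half[j]) / slope[j]))
            else:
                m[j] = 1.0
            gtot += g_ns[j] * m[j]
            gsum_e += g_ns[j] * m[j] * e_rev[j]
        if rs_gohm > 0.0:
            vm = (vc[0] / rs_gohm + gsum_e) / (gtot + 1.0 / rs_gohm)
        else:
            vm = vc[0]
            break

    for k in range(n):
        vck = vc[k]
        q_pipette = 0.0  # pA*ms moved through the pipette this interval
        for _ in range(nsub):
            gtot = g_leak
            gsum_e = g_leak * e_leak
            for j in range(nch):
                if gated[j]:
                    minf = 1.0 / (1.0 + math.exp(-(vm - v_half[j]) / slope[j]))
                    tau = tau_act[j] if minf > m[j] else tau_deact[j]
                    m[j] = minf + (m[j] - minf) * math.exp(-dts / tau)
                gtot += g_ns[j] * m[j]
                gsum_e += g_ns[j] * m[j] * e_rev[j]
            if rs_gohm > 0.0:
                g_all = gtot + 1.0 / rs_gohm
                vinf = (vck / rs_gohm + gsum_e) / g_all
                tau_v = cm / g_all
                decay = math.exp(-dts / tau_v)
                # exact integral of Vm over the substep (frozen gates):
                # charge through Rs is conserved even when tau_v << dt
                vm_int = vinf * dts + (vm - vinf) * tau_v * (1.0 - decay)
                q_pipette += (vck * dts - vm_int) / rs_gohm
                vm = vinf + (vm - vinf) * decay
            else:
                vm = vck
        if rs_gohm > 0.0:
            # interval-averaged pipette current, as the analog acquisition
            # chain (continuous-time filtering before sampling) would report
            i_rec[k] = q_pipette / dt
        else:
            # ideal clamp: membrane current plus the capacitive charge moved
            # by the command change over this interval (backward difference)
            i_ion = g_leak * (vck - e_leak)
            for j in range(nch):
                i_ion += g_ns[j] * m[j] * (vck - e_rev[j])
            dv = vck - vc[k - 1] if k > 0 else 0.0
            i_rec[k] = i_ion + cm * dv / dt
    return i_rec


def _bessel_filter(current: np.ndarray, sampling_khz: float, filter_khz: float) -> np.ndarray:
    """Digital (bilinear-transformed) 3-pole Bessel low-pass, causal."""
    if filter_khz <= 0:
        return current
    b, a = signal.bessel(3, filter_khz, btype="low", fs=sampling_khz, norm="mag")
    return signal.lfilter(b, a, current, axis=-1)


def simulate_sweep(
    cell: SimCellParams,
    protocol: ProtocolSpec,
    solution: str = "tyrode_ca",
    drug: str = "none",
    seed: int | np.random.Generator | None = None,
    substeps: int = 10,
) -> SweepRecording:
    """Simulate one (averaged) voltage-clamp sweep for a synthetic cell.

    ``n_sweep_avg`` independent noisy realisations are Bessel-filtered and
    averaged, mirroring the acquisition chain (noise -> filter -> average).
    ``seed`` may be an int or a ``numpy.random.Generator``; it is required
    whenever ``cell.noise_sd > 0``.
    """
    if cell.noise_sd > 0 and seed is None:
        raise ValueError("seed is required when noise_sd > 0")
    vc = command_waveform(protocol)
    specs = cell.channels
    nch = max(len(specs), 1)
    g_ns = np.zeros(nch)
    e_rev = np.zeros(nch)
    v_half = np.zeros(nch)
    slope = np.ones(nch)
    tau_act = np.ones(nch)
    tau_deact = np.ones(nch)
    gated = np.zeros(nch, dtype=np.bool_)
    for j, ch in enumerate(specs):
        g_ns[j] = (
            ch.g_density * cell.cm / 1000.0
            * ch.solution_scale(solution)
            * ch.drug_scale(drug)
        )
        e_rev[j] = ch.e_rev
        v_half[j] = ch.v_half
        slope[j] = ch.slope
        tau_act[j] = ch.tau_act
        tau_deact[j] = ch.tau_deact
        gated[j] = ch.family != "leak"

    dt = protocol.dt_ms
    current = _integrate_clamp(
        vc, dt, substeps, cell.cm, 1.0 / cell.rm, cell.e_leak,
        cell.rs / 1000.0, g_ns, e_rev, v_half, slope, tau_act, tau_deact, gated,
    )
    if not np.all(np.isfinite(current)):
        bad = int(np.argmax(~np.isfinite(current)))
        for idx, (lo, hi) in enumerate(segment_bounds(protocol)):
            if lo <= bad < hi:
                seg = protocol.segments[idx]
                raise IntegrationError(
                    f"non-finite state in segment {idx} "
                    f"({seg.kind} {seg.v_start:+.0f}->{seg.v_end:+.0f} mV)"
                )
        raise IntegrationError("non-finite state during integration")

    if cell.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        noisy = current + rng.normal(0.0, cell.noise_sd, (protocol.n_sweep_avg, len(current)))
        filtered = _bessel_filter(noisy, protocol.sampling_khz, protocol.filter_khz)
        current = filtered.mean(axis=0)
    else:
        current = _bessel_filter(current, protocol.sampling_khz, protocol.filter_khz)

    time = np.arange(len(vc)) * dt
    return SweepRecording(
        time=time,
        current=current,
        protocol=protocol,
        solution=solution,
        drug=drug,
        cell_id=cell.cell_id,
        genotype=cell.genotype,
        day=cell.day,
        cm_pf=cell.cm,
    )


# ---------------------------------------------------------------------------
# default fixture cells and population generator
# ---------------------------------------------------------------------------


def _default_channels(genotype: str, g_scale: dict[str, float] | None = None) -> tuple[ChannelSpec, ...]:
    """Channel battery with calibrated genotype densities (pS/pF).

    cln1 carries 25% of the mock vgcc and kv12 densities; kv11 is equal.
    Kinetics are calibration choices (the cell line's Kv constants are not
    published): kv11 fast-deactivating, kv12 slowly-deactivating.
    """
    mock = genotype == "mock"
    dens = {
        "kv11": 30.0,
        "kv12": 60.0 if mock else 15.0,
        "vgcc": 12.0 if mock else 3.0,
    }
    if g_scale:
        for k, v in g_scale.items():
            dens[k] = v
    return (
        ChannelSpec(
            family="kv11", g_density=dens["kv11"], e_rev=E_K,
            v_half=-40.0, slope=12.0, tau_act=500.0, tau_deact=30.0,
            block_4ap=1.0,
        ),
        ChannelSpec(
            family="kv12", g_density=dens["kv12"], e_rev=E_K,
            v_half=-8.0, slope=10.0, tau_act=500.0, tau_deact=300.0,
            potentiate_4ap=1.3, block_ns=1.0,
        ),
        ChannelSpec(
            family="vgcc", g_density=dens["vgcc"], e_rev=60.0,
            v_half=0.0, slope=7.0, tau_act=2.0, tau_deact=2.0,
            carrier_gain_ba=6.0,
        ),
    )


def _cell_from_primitives(
    genotype: str, cm: float, g_leak_density: float, rs: float, day: int,
    noise_sd: float, cell_id: str, g_scale: dict[str, float] | None = None,
    e_leak: float = -79.0,
) -> SimCellParams:
    rm = 1000.0 / (g_leak_density * cm)  # GOhm from pS/pF * pF
    return SimCellParams(
        cm=cm, rm=rm, rs=rs, e_leak=e_leak,
        channels=_default_channels(genotype, g_scale),
        genotype=genotype, day=day, noise_sd=noise_sd, cell_id=cell_id,
    )


def mock_default(noise_sd: float = 0.0) -> SimCellParams:
    """Representative mock-transfected fixture: 28 pF, ~35 pS/pF leak."""
    return _cell_from_primitives("mock", 28.0, 35.0, 6.0, 5, noise_sd, "mock_default")


def cln1_default(noise_sd: float = 0.0) -> SimCellParams:
    """Representative CLN1-overexpressing fixture: 14 pF, ~32 pS/pF leak."""
    return _cell_from_primitives("cln1", 14.0, 32.0, 6.0, 5, noise_sd, "cln1_default")


def default_population_config() -> dict:
    """Genotype-level generative moments for population draws.

    Means anchor to the printed group values: mock/cln1 Cm 28/14 pF with day
    drifts -1.08/-0.98 pF per day (centred on the middle of the recorded day
    range), leak densities 35/32 pS/pF, vgcc and kv12 densities reduced to
    25% in cln1.  CVs are the package's realism choices.
    """
    return {
        "mock": {
            "cm_mean": 28.0, "cm_cv": 0.22, "cm_day_slope": -1.08,
            "g_leak_mean": 35.0, "g_leak_cv": 0.30,
            "rs_mean": 6.0, "rs_cv": 0.25,
            "e_leak": -79.0, "noise_sd": 4.0,
            "channel_cv": 0.35,
            "g_density": {"kv11": 30.0, "kv12": 60.0, "vgcc": 12.0},
        },
        "cln1": {
            "cm_mean": 14.0, "cm_cv": 0.22, "cm_day_slope": -0.98,
            "g_leak_mean": 32.0, "g_leak_cv": 0.20,
            "rs_mean": 6.0, "rs_cv": 0.25,
            "e_leak": -79.0, "noise_sd": 4.0,
            "channel_cv": 0.35,
            "g_density": {"kv11": 30.0, "kv12": 15.0, "vgcc": 3.0},
        },
    }


def kv12_decline_config(zero_day: float = 7.0) -> dict:
    """Population config where mock Kv12 density falls linearly to 0.

    Models the loss of functional Kv12 channels with time after
    differentiation: the mock mean density declines to zero by
    ``zero_day``, so the 4-AP tail ratio acquires a negative day slope.
    """
    config = default_population_config()
    config["mock"]["kv12_zero_day"] = zero_day
    return config


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Log-normal draw parameterised by arithmetic mean and CV."""
    if cv <= 0:
        return np.full(size, mean) if size else mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def draw_population_params(
    config: dict | None,
    n_mock: int,
    n_cln1: int,
    day_range: tuple[int, int] = (3, 10),
    seed: int | np.random.Generator | None = None,
) -> list[SimTruth]:
    """Draw per-cell generative parameters (log-normal for positive scales)."""
    if n_mock <= 0 or n_cln1 <= 0:
        raise ValueError("n_mock and n_cln1 must be > 0")
    config = config or default_population_config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    day_ref = 0.5 * (day_range[0] + day_range[1])
    truths: list[SimTruth] = []
    for genotype, n in (("mock", n_mock), ("cln1", n_cln1)):
        block = config[genotype]
        for i in range(n):
            day = int(rng.integers(day_range[0], day_range[1] + 1))
            cm_mean = block["cm_mean"] + block["cm_day_slope"] * (day - day_ref)
            cm = float(_lognormal(rng, max(cm_mean, 2.0), block["cm_cv"]))
            g_leak = float(_lognormal(rng, block["g_leak_mean"], block["g_leak_cv"]))
            rs = float(min(_lognormal(rng, block["rs_mean"], block["rs_cv"]), 79.0))
            g_scale = {}
            for fam, mean in block["g_density"].items():
                if fam == "kv12" and "kv12_zero_day" in block:
                    # linear loss of Kv12 with time in culture, reaching
                    # zero at kv12_zero_day (day-interaction fixture)
                    mean = mean * max(0.0, 1.0 - day / block["kv12_zero_day"])
                g_scale[fam] = float(_lognormal(rng, mean, block["channel_cv"])) if mean > 0 else 0.0
            cell = _cell_from_primitives(
                genotype, cm, g_leak, rs, day, block["noise_sd"],
                f"{genotype}_{i:03d}", g_scale, block["e_leak"],
            )
            truths.append(
                SimTruth(
                    params=cell,
                    cm=cm,
                    g_leak_ns=1.0 / cell.rm,
                    g_density={ch.family: ch.g_density for ch in cell.channels},
                    v_half={ch.family: ch.v_half for ch in cell.channels},
                    slope={ch.family: ch.slope for ch in cell.channels},
                )
            )
    return truths


@dataclass
class PopulationCell:
    """Sweep battery plus ground truth for one simulated cell."""

    truth: SimTruth
    sweeps: dict[str, object] = field(default_factory=dict)


def simulate_population(
    config: dict | None = None,
    n_mock: int = 15,
    n_cln1: int = 15,
    day_range: tuple[int, int] = (3, 10),
    seed: int | None = 0,
    protocols: Sequence[str] = ("capacitance", "ramp_ca", "ramp_ba"),
) -> list[PopulationCell]:
    """Simulate a population and its protocol battery.

    ``protocols`` selects which recordings to generate per cell:
    ``capacitance`` (45 ms step), ``ramp_ca`` / ``ramp_ba`` (voltage ramps in
    Tyrode / Ba-TEA), ``tails`` (the 15-step 2 s battery), and ``pharm``
    (+70 mV tails recorded sequentially in Tyrode, 4-AP, 4-AP + NS-1643).
    """
    rng = np.random.default_rng(seed)
    truths = draw_population_params(config, n_mock, n_cln1, day_range, rng)
    cells = []
    cap = capacitance_protocol()
    ramp = ramp_protocol()
    for truth in truths:
        p = truth.params
        sweeps: dict[str, object] = {}
        if "capacitance" in protocols:
            sweeps["capacitance"] = simulate_sweep(p, cap, seed=rng)
        if "ramp_ca" in protocols:
            sweeps["ramp_ca"] = simulate_sweep(p, ramp, solution="tyrode_ca", seed=rng)
        if "ramp_ba" in protocols:
            sweeps["ramp_ba"] = simulate_sweep(p, ramp, solution="ba_tea", seed=rng)
        if "tails" in protocols:
            sweeps["tails"] = {
                v: simulate_sweep(p, tail_protocol(v), seed=rng) for v in TAIL_VOLTAGES
            }
        if "pharm" in protocols:
            sweeps["pharm"] = {
                drug: simulate_sweep(p, tail_protocol(70.0), drug=drug, seed=rng)
                for drug in DRUGS
            }
        cells.append(PopulationCell(truth=truth, sweeps=sweeps))
    return cells


# ---------------------------------------------------------------------------
# fluorescence and expression generators
# ---------------------------------------------------------------------------


def simulate_fluorescence_traces(
    n_mock: int = 132,
    n_cln1: int = 40,
    stim_window_s: tuple[float, float] = (60.0, 90.0),
    seed: int | None = 0,
    duration_s: float = 150.0,
    frame_interval_s: float = 2.0,
    amp_mean: dict[str, float] | None = None,
    amp_cv: float = 0.5,
    noise_sd: float = 0.01,
    tau_on_s: float = 4.0,
    tau_off_s: float = 20.0,
) -> list[FluorescenceTrace]:
    """Fluo-4-like traces for a KCl depolarisation window.

    Baseline F0 carries multiplicative noise; during the stimulus F rises
    with a single-exponential onset toward ``F0 * (1 + A)`` and decays
    exponentially afterwards.  A is drawn per genotype (log-normal), with the
    cln1 mean amplitude below the mock mean; truth A is recorded per trace.
    """
    if not (0.0 <= stim_window_s[0] < stim_window_s[1] <= duration_s):
        raise ValueError("stim window must lie inside the trace span")
    rng = np.random.default_rng(seed)
    amp_mean = amp_mean or {"mock": 0.6, "cln1": 0.3}
    t = np.arange(0.0, duration_s + 1e-9, frame_interval_s)
    t0, t1 = stim_window_s
    traces = []
    for genotype, n in (("mock", n_mock), ("cln1", n_cln1)):
        a_mean = amp_mean[genotype]
        for i in range(n):
            day = int(rng.integers(3, 11))
            f0 = float(_lognormal(rng, 100.0, 0.3))
            a = float(_lognormal(rng, a_mean, amp_cv)) if a_mean > 0 else 0.0
            shape = np.zeros_like(t)
            during = (t >= t0) & (t <= t1)
            shape[during] = 1.0 - np.exp(-(t[during] - t0) / tau_on_s)
            after = t > t1
            peak = 1.0 - math.exp(-(t1 - t0) / tau_on_s)
            shape[after] = peak * np.exp(-(t[after] - t1) / tau_off_s)
            f = f0 * (1.0 + a * shape)
            if noise_sd > 0:
                f = f * (1.0 + rng.normal(0.0, noise_sd, len(t)))
            traces.append(
                FluorescenceTrace(
                    t=t, f=f, stim_window=stim_window_s,
                    roi_id=f"{genotype}_roi{i:03d}", genotype=genotype, day=day,
                    true_amplitude=a,
                )
            )
    return traces


def simulate_expression_table(
    n_genes: int = 1000,
    n_deg: int = 50,
    effect_range: tuple[float, float] = (1.2, 2.5),
    seed: int | None = 0,
    noise_sd_log2: float = 0.05,
):
    """FPKM table for two conditions with known differential-expression truth.

    True DEGs receive a log2 effect drawn from ``effect_range`` (random
    sign) and a q-value <= 0.05; null genes draw q uniformly on (0, 1), so
    ~95% of them sit above the 0.05 cutoff.  Returns a pandas DataFrame with
    columns gene, fpkm_a, fpkm_b, q, true_log2fc, is_true_deg.
    """
    import pandas as pd

    if n_deg > n_genes:
        raise ValueError("n_deg must be <= n_genes")
    if effect_range[0] < 1.0:
        raise ValueError("true DEG effects must satisfy |effect| >= 1 (log2 units)")
    rng = np.random.default_rng(seed)
    base = _lognormal(rng, 10.0, 2.0, n_genes)
    true_fc = np.zeros(n_genes)
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    if n_deg:
        mag = rng.uniform(effect_range[0], effect_range[1], n_deg)
        sign = rng.choice([-1.0, 1.0], n_deg)
        true_fc[deg_idx] = mag * sign
    fpkm_a = base * 2.0 ** rng.normal(0.0, noise_sd_log2, n_genes)
    fpkm_b = base * 2.0 ** (true_fc + rng.normal(0.0, noise_sd_log2, n_genes))
    q = rng.uniform(0.0, 1.0, n_genes)
    q[deg_idx] = rng.uniform(1e-4, 0.05, n_deg)
    is_deg = np.zeros(n_genes, dtype=bool)
    is_deg[deg_idx] = True
    return pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(n_genes)],
            "fpkm_a": fpkm_a,
            "fpkm_b": fpkm_b,
            "q": q,
            "true_log2fc": true_fc,
            "is_true_deg": is_deg,
        }
    )
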