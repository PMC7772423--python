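"""Tail-current analysis: windows, fractional activation, Boltzmann fits."""

from __future__ import annotations

import numpy as np
import pytest

from ionclamp import simulate as sim
from ionclamp import tails
from ionclamp.simulate import ChannelSpec, ProtocolSpec, Segment, SimCellParams, SweepRecording


def _tail_proto(fs_khz=1.0, filter_khz=0.0):
    return ProtocolSpec(
        segments=(
            Segment("hold", -80.0, -80.0, 200.0),
            Segment("step", 30.0, 30.0, 2000.0),
            Segment("step", -50.0, -50.0, 1000.0),
        ),
        sampling_khz=fs_khz,
        filter_khz=filter_khz,
    )


def _manual_sweep(proto, current):
    return SweepRecording(
        time=np.arange(len(current)) / proto.sampling_khz, current=current, protocol=proto
    )


def test_steady_state_window_definition():
    """Result is exactly the mean of the final 200 samples at 1 kHz."""
    proto = _tail_proto()
    n = proto.n_samples()
    current = np.full(n, 100.0)
    current[-1200:-1000] = 137.5  # inside the last 200 ms of the 2 s step
    sweep = _manual_sweep(proto, current)
    window = sweep.current[3200 - 1200:3200 - 1000]
    assert tails.steady_state_current(sweep, cm=20.0) == pytest.approx(
        float(window.mean()) / 20.0
    )
    assert tails.steady_state_current(_manual_sweep(proto, np.full(n, 100.0)), 20.0) == 5.0


def test_steady_state_matches_analytic_kv():
    """Simulated Kv current, tau 100 ms: within 1% of g*minf*(V - EK)."""
    ch = ChannelSpec("kv12", 50.0, -85.0, v_half=-20.0, slope=10.0,
                     tau_act=100.0, tau_deact=100.0)
    cell = SimCellParams(cm=20.0, rm=2.0, rs=0.0, e_leak=-80.0, channels=(ch,))
    sweep = sim.simulate_sweep(cell, _tail_proto())
    minf = 1.0 / (1.0 + np.exp(-(30.0 + 20.0) / 10.0))
    expected = (50.0 * 20.0 / 1000.0 * minf * (30.0 + 85.0) + (30.0 + 80.0) / 2.0) / 20.0
    assert tails.steady_state_current(sweep, 20.0) == pytest.approx(expected, rel=0.01)


def test_steady_state_window_longer_than_step_errors():
    proto = _tail_proto()
    sweep = _manual_sweep(proto, np.zeros(proto.n_samples()))
    with pytest.raises(ValueError, match="window"):
        tails.steady_state_current(sweep, 20.0, window_ms=3000.0)


def test_tail_amplitude_square_pulse_and_zero():
    """A 50 pA square tail with cm=10 reads 5 pA/pF; a flat tail reads 0."""
    proto = _tail_proto()
    n = proto.n_samples()
    current = np.zeros(n)
    current[2200:2200 + 400] = 50.0  # 400 ms square pulse from tail onset
    sweep = _manual_sweep(proto, current)
    assert tails.tail_amplitude(sweep, cm=10.0) == pytest.approx(5.0)
    assert tails.tail_amplitude(_manual_sweep(proto, np.zeros(n)), 10.0) == 0.0


def test_tail_window_matches_high_rate_oracle(mock_cell):
    """1 kHz tail window mean within 3% of a 10 kHz re-simulation."""
    proto_lo = _tail_proto(fs_khz=1.0)
    proto_hi = _tail_proto(fs_khz=10.0)
    lo = sim.simulate_sweep(mock_cell, proto_lo)
    hi = sim.simulate_sweep(mock_cell, proto_hi)
    latency = tails.tail_peak_latency(lo)
    a = tails.tail_amplitude(lo, mock_cell.cm, latency)
    b = tails.tail_amplitude(hi, mock_cell.cm, latency)
    assert a == pytest.approx(b, rel=0.03)


def test_fractional_activation_arithmetic_and_endpoints():
    curve = tails.ActivationCurve(
        activating_v=np.array([-70.0, 0.0, 70.0]),
        tail_amp=np.array([1.0, 3.0, 5.0]),
        i_minus70=1.0,
        i_max=5.0,
    )
    fa = tails.fractional_activation(curve)
    np.testing.assert_allclose(fa, [0.0, 0.5, 1.0])

    flat = tails.ActivationCurve(
        activating_v=np.array([-70.0, 0.0]), tail_amp=np.array([2.0, 2.0]),
        i_minus70=2.0, i_max=2.0,
    )
    with pytest.raises(ValueError, match="undefined activation"):
        tails.fractional_activation(flat)


def test_fractional_activation_preserves_order(rng):
    """Monotone tail amplitudes map to monotone FA (affine map)."""
    amps = np.sort(rng.uniform(0.5, 5.0, 15))
    curve = tails.ActivationCurve(
        activating_v=np.arange(-70.0, 80.0, 10.0), tail_amp=amps,
        i_minus70=float(amps[0]), i_max=float(amps[-1]),
    )
    fa = tails.fractional_activation(curve)
    assert np.all(np.diff(fa) >= 0)
    assert fa[0] == 0.0 and fa.max() == 1.0


def test_activation_curve_invariants_on_fixture_cells(tail_batteries):
    for genotype, battery in tail_batteries.items():
        cm = battery[30.0].cm_pf
        curve = tails.activation_curve(battery, cm)
        fa = tails.fractional_activation(curve)
        assert fa[np.argmin(np.abs(curve.activating_v + 70.0))] == 0.0
        assert fa.max() == 1.0
        assert not curve.latency_fallback


def test_missing_reference_sweep_falls_back(tail_batteries):
    battery = {v: s for v, s in tail_batteries["mock"].items() if v != 30.0}
    curve = tails.activation_curve(battery, battery[70.0].cm_pf)
    assert curve.latency_fallback


def test_boltzmann_eval_values():
    assert tails.boltzmann_eval(-20.0, -20.0, 10.0) == 0.5
    assert tails.boltzmann_eval(1000.0, -20.0, 10.0) == pytest.approx(1.0)
    assert tails.boltzmann_eval(-1000.0, -20.0, 10.0) == pytest.approx(0.0)
    assert tails.boltzmann_eval(0.0, -20.0, 10.0) == pytest.approx(0.8808, abs=1e-4)
    with pytest.raises(ValueError):
        tails.boltzmann_eval(0.0, -20.0, 0.0)


def test_fit_exact_recovery_on_noiseless_data():
    v = np.arange(-70.0, 80.0, 10.0)
    y = tails.boltzmann_eval(v, -20.0, 10.0)
    fit = tails.fit_boltzmann(v, y)
    assert fit.converged
    assert fit.v_half == pytest.approx(-20.0, abs=1e-6)
    assert fit.slope_s == pytest.approx(10.0, abs=1e-6)


def test_fit_noisy_recovery_is_efficient(rng):
    """Under additive noise the fit attains the information-theoretic floor.

    With sigma = 0.05 on the 15-point grid the Fisher information for V0.5
    (slope jointly estimated) bounds the estimator sd from below; the fit
    should be unbiased and sit within ~25% of that bound, with no gross
    outliers (all errors inside 5 sd).
    """
    v = np.arange(-70.0, 80.0, 10.0)
    vh, s, sigma = -20.0, 10.0, 0.05
    truth = tails.boltzmann_eval(v, vh, s)
    dfa = truth * (1 - truth)
    # CRLB for (v_half, slope): invert the 2x2 Fisher information
    grad = np.column_stack([dfa / s, dfa * (v - vh) / s**2])
    crlb_sd = np.sqrt(np.linalg.inv(grad.T @ grad / sigma**2)[0, 0])
    errors = np.array([
        tails.fit_boltzmann(v, truth + rng.normal(0, sigma, len(v))).v_half - vh
        for _ in range(300)
    ])
    assert abs(errors.mean()) < 3 * crlb_sd / np.sqrt(len(errors))
    assert errors.std(ddof=1) < 1.25 * crlb_sd
    assert np.all(np.abs(errors) < 5 * crlb_sd)


def test_fit_rss_beats_dense_grid(rng):
    """Optimizer RSS within 1e-4 of a 0.1 x 0.1 grid-search oracle."""
    v = np.arange(-70.0, 80.0, 10.0)
    y = tails.boltzmann_eval(v, -25.0, 9.0) + rng.normal(0, 0.05, len(v))
    fit = tails.fit_boltzmann(v, y)
    vh_grid = np.arange(-50.0, 0.0, 0.1)
    s_grid = np.arange(2.0, 30.0, 0.1)
    pred = 1.0 / (1.0 + np.exp(-(v[None, None, :] - vh_grid[:, None, None]) / s_grid[None, :, None]))
    rss = ((pred - y[None, None, :]) ** 2).sum(axis=-1)
    assert fit.rss <= rss.min() + 1e-4


def test_fit_voltage_shift_reparameterization():
    v = np.arange(-70.0, 80.0, 10.0)
    y = tails.boltzmann_eval(v, -22.0, 11.0)
    base = tails.fit_boltzmann(v, y)
    shifted = tails.fit_boltzmann(v + 15.0, y)
    assert shifted.v_half == pytest.approx(base.v_half + 15.0, abs=1e-6)
    assert shifted.slope_s == pytest.approx(base.slope_s, abs=1e-6)


def test_fit_contract_errors():
    v = np.array([-20.0, 0.0, 20.0])
    with pytest.raises(ValueError, match="4 points"):
        tails.fit_boltzmann(v, tails.boltzmann_eval(v, 0.0, 10.0))
    v = np.arange(-70.0, 80.0, 10.0)
    with pytest.raises(ValueError, match="all y"):
        tails.fit_boltzmann(v, np.ones_like(v))


def test_conductance_mode_fit_recovers_simulator_gating():
    """Free-amplitude fit of steady-state conductance: V0.5/S within 0.5 mV."""
    ch = ChannelSpec("kv12", 60.0, -85.0, v_half=-15.0, slope=9.0,
                     tau_act=30.0, tau_deact=30.0)
    cell = SimCellParams(cm=20.0, rm=100.0, rs=0.0, e_leak=-85.0, channels=(ch,))
    voltages = np.arange(-70.0, 80.0, 10.0)
    g_norm = []
    for v_step in voltages:
        proto = ProtocolSpec(
            segments=(
                Segment("hold", -80.0, -80.0, 200.0),
                Segment("step", v_step, v_step, 2000.0),
                Segment("step", -50.0, -50.0, 500.0),
            ),
            sampling_khz=1.0,
        )
        sweep = sim.simulate_sweep(cell, proto)
        iss = tails.steady_state_current(sweep, cell.cm)
        g_norm.append(iss / (v_step + 85.0) * 1000.0 if v_step != -85.0 else 0.0)
    fit = tails.fit_boltzmann(voltages, np.array(g_norm), fix_amplitude=False)
    assert fit.v_half == pytest.approx(-15.0, abs=0.5)
    assert fit.slope_s == pytest.approx(9.0, abs=0.5)
    assert fit.amplitude == pytest.approx(60.0, rel=0.02)


def test_fixture_tail_vhalf_matches_reported_group_means(tail_batteries):
    """Calibrated fixtures land near the reported -14.6 / -25.8 mV."""
    expected = {"mock": -14.6, "cln1": -25.8}
    for genotype, battery in tail_batteries.items():
        cm = battery[30.0].cm_pf
        curve = tails.activation_curve(battery, cm)
        fit = tails.fit_boltzmann(curve.activating_v, tails.fractional_activation(curve))
        assert fit.v_half == pytest.approx(expected[genotype], abs=2.5)
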