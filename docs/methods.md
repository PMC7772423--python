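# Methods

## The synthetic cell and the clamp circuit

Every recording the package analyses can be generated by
`ionclamp.simulate`, which models a perforated-patch voltage-clamp
experiment as the standard two-node circuit: a pipette at command voltage
`Vc` connected through a series resistance `Rs` to a membrane node `Vm`
carrying capacitance `Cm`, a passive leak `(Vm − E_leak)/Rm`, and up to
three gated conductance families,

```
Cm dVm/dt = (Vc − Vm)/Rs − Σ_f g_f m_f (Vm − E_f) − (Vm − E_leak)/Rm ,
```

with the recorded quantity being the pipette current `(Vc − Vm)/Rs`.
Units are mV/ms/pA/pF/GΩ/nS throughout, so all conversions are powers of
ten at module boundaries.

Each gated family has a single activation gate `m` relaxing first-order
toward a Boltzmann steady state `m∞(V) = 1/(1 + e^−(V−V½)/s)` with time
constant `tau_act` when opening and `tau_deact` when closing. There is no
inactivation: the analyses downstream measure activation only, and a
minimal model keeps every stage interpretable against closed forms.

**Integration.** Exponential-Euler updates (exact for the membrane equation
with gates frozen, and for each gate with `m∞` frozen) at 10 substeps per
sample. The command is zero-order-held over each sample interval, and the
recorded sample is the **interval-averaged** pipette current, computed from
the analytic integral of `Vm` over each substep. This mirrors what a
continuous-time acquisition chain delivers and makes the scheme exactly
charge-conserving even when the clamp time constant `Cm·(Rs‖Rm)` drops
below the sample interval. With `Rs = 0` the clamp is ideal (`Vm = Vc`) and
the capacitive current is added as `Cm ΔVc/Δt` (backward difference).

**Acquisition chain.** Per-sample Gaussian current noise (`noise_sd`, pA)
is added to the clean trace, each realisation is filtered by a digital
(bilinear-transformed, magnitude-normalised) 3-pole Bessel low-pass, and
`n_sweep_avg` realisations are averaged — noise → filter → average, in that
order. Protocol defaults follow the acquisition settings of the study the
package models: capacitance steps 50 kHz/5 kHz/64 sweeps, ramps
5 kHz/1 kHz/16 sweeps, 2 s steps 1 kHz/0.3 kHz. Drugs and bath changes are
instantaneous, stateless conductance rescalings: 4-AP multiplies each
family by `(1 − block_4ap)·potentiate_4ap`, NS-1643 (given on top of 4-AP)
by `(1 − block_ns)`, and the Ba²⁺/TEA bath zeroes the Kv families while
multiplying the VGCC by `carrier_gain_ba` (default 6). Junction potentials
are never applied.

**Default fixtures and calibration.** The representative cells are
`mock_default` (28 pF, leak 35 pS/pF) and `cln1_default` (14 pF,
32 pS/pF), with `E_leak = −79 mV` chosen so the holding-current density at
−90 mV lands near −0.4 pA/pF, `E_K = −85 mV` (Nernst for 5/140 mM K⁺), and
`Rs = 6 MΩ`. The CLN1 genotype carries 25% of the mock VGCC and Kv12
densities and the same Kv11 density. Kinetic constants for the KCNH
families in this cell type are not published; they are calibration choices,
frozen once: Kv11 `V½ = −40 mV, s = 12 mV, tau_act = 500 ms,
tau_deact = 30 ms`; Kv12 `V½ = −8 mV, s = 10 mV, tau_act = 500 ms,
tau_deact = 300 ms`; VGCC `V½ = 0 mV, s = 7 mV, tau = 2 ms, E = +60 mV`
(placing the ramp inward peak near +10 mV). The Kv midpoints were tuned so
the *tail-derived* half-activation voltages of the two fixtures land at
−14.1 and −26.3 mV, matching the reported group means (−14.6 ± 3.8 and
−25.8 ± 3.2 mV): the measured tail V½ is a density-weighted blend of the
two families' activation curves, so the genotype difference emerges from
the Kv12/Kv11 density ratio, not from per-genotype gating parameters.

**Populations.** `simulate_population` draws per-cell parameters
log-normally (parameterised by arithmetic mean and CV) from genotype
blocks anchored to the printed group values: Cm means 28/14 pF with day
drifts −1.08/−0.98 pF/day centred on the middle of the 3–10 day culture
window, leak densities 35/32 pS/pF, channel-density CV 0.35, noise 4 pA.
Days are uniform integers over the configured range. An optional
`kv12_zero_day` drives the mock Kv12 density linearly to zero with days in
culture, reproducing the observed time-dependence of 4-AP sensitivity.

Fluorescence traces emulate Fluo-4 imaging at one frame per 2 s: baseline
`F0` (log-normal, 30% CV) with 1% multiplicative frame noise, a
single-exponential rise (τ = 4 s) toward `F0·(1+A)` during the 30 s
high-K⁺ window and exponential decay (τ = 20 s) afterwards; the response
amplitude `A` is log-normal with genotype means 0.6 (mock) and 0.3 (CLN1),
CV 0.5, and is recorded as truth. Expression tables draw base FPKM
log-normally, add a ±(1.2–2.5) log₂ effect to a chosen subset of genes
(q ≤ 0.05 for those; uniform q otherwise) with 0.05 log₂-units of
measurement noise per condition.

## Analysis conventions and numerical choices

* **Capacitance.** ΔQ is the trapezoidal integral of the
  baseline-subtracted current from step onset to step end, where the
  baseline is the mean over the final 10 ms of the step (the steady state
  at −70 mV); `Cm = ΔQ/ΔV`. Integration starts one sample before the first
  step-command sample — that sample *is* the onset instant under zero-order
  hold, and starting there gives the transient's first sample full interior
  trapezoid weight. Only the on-transient is integrated. `Rm = ΔV/ΔI` with
  `ΔI` between the step-end and holding means (final 10 ms of each); net
  changes below 0.1 pA return infinite resistance.
* **Series-resistance bias (documented, not corrected).** For this circuit
  the charge estimate is attenuated by `(Rm/(Rm+Rs))²` and the resistance
  estimate is shifted by `+Rs`; at the fixture values (Rs = 6 MΩ,
  Rm ≈ 1 GΩ) that is ≈1.2% on Cm. A second acquisition artifact is the
  causal filter's group delay, which bleeds the pre-step/baseline current
  offset into the charge window (≈ `τ_delay·ΔI`, ≈0.2% for GΩ-range cells).
  Estimator-consistency tests therefore run with the filter off; analyses
  of filtered data inherit the (small) bias exactly as a rig would.
* **Ramp I–V.** The leak line is an OLS fit of current against *commanded*
  voltage over −90..−40 mV (below the activation range of every modelled
  conductance — the window is a package choice), excluding the first 5 ms
  of the ramp, where the filter warm-up would act as high-leverage
  outliers. The net peak is the minimum of the 5-point median-smoothed
  residual within −30..+40 mV, normalised by Cm; residuals that never drop
  below −1 pA (the extrapolation-error floor) are flagged `no_deflection`.
  Note the constant capacitive ramp current `Cm·dV/dt` is absorbed by the
  line's intercept and cancels from the residual.
* **Tails.** The tail peak is located on the +30 mV sweep (the largest
  smoothed excursion from the late-tail baseline, either polarity),
  skipping the first 20 ms of the tail where the filtered repolarisation
  transient would masquerade as the peak; the 20 ms measurement window is
  then applied *at that fixed latency* to every activating voltage of the
  cell. Fractional activation uses raw (not baseline-subtracted) tail
  values — shared leak current cancels through the I₋₇₀ reference. Drug
  ratios instead subtract the late-tail baseline, so a fully blocked cell
  reads zero and the ratios obey the conductance algebra
  `Σ g_f s_f w_f / Σ g_f w_f` exactly in the noise-free, unfiltered limit.
* **Boltzmann fits.** Unweighted nonlinear least squares; amplitude fixed
  at 1 for fractional-activation data, free for conductance data;
  initialisation at the abscissa closest to half-range with s = 10 mV;
  slope bounded to (0.5, 100] mV; non-convergence returns the best iterate,
  flagged. Shifting all voltages by +c shifts V½ by +c and leaves s
  unchanged (tested).
* **Expression.** log₂FC uses the CLN1 condition in the numerator;
  zero/negative FPKM yields an undefined (never-flagged) fold change unless
  a pseudocount is explicitly enabled. DEG thresholds are inclusive. The
  packaged channel table keeps both the printed log₂FC and the recomputed
  value so rounding (FPKMs are printed at 2 decimals) and logic errors stay
  distinguishable. q-values are consumed, never computed: FDR control
  belongs to the upstream RNA-seq pipeline.
* **Statistics.** The t-test pools variances by default — this reproduces
  the published df pattern (27/28/26) and t values from mean/SEM/n triplets
  exactly; Welch is behind a flag. Mann-Whitney uses exact enumeration for
  tie-free samples with n₁+n₂ ≤ 12 and the tie-corrected normal
  approximation otherwise. ANCOVA reports sequential (Type I) F tests in
  both term orders plus Type II, because published legends that show factor
  F(1,27) next to covariate F(1,26) for n = 30 cannot come from a single
  fixed model; the primary report is the factor-first order. The mixed
  ANOVA (between-genotype × within-condition) is computed by
  `pingouin.mixed_anova` and cross-checked in the tests against an explicit
  cell-means sums-of-squares decomposition; all-equal input returns F = 0
  by convention.

## What the generator does and does not emulate

The simulator reproduces the statistical structure the analyses assume:
RC-transient charge, linear leak plus Boltzmann-gated currents,
series-resistance voltage errors, filter and averaging effects, per-cell
log-normal variability, day drifts, and drug/bath conductance rescaling.
It does **not** model ion permeation (GHK), Ca²⁺ buffering, perfusion
kinetics, inactivation, stochastic channel gating or current-clamp
behaviour. Two visible consequences: in normal (2 mM Ca²⁺) Tyrode the
modelled VGCC current stays below the Kv background on the ramp, so the
Ca²⁺-carrier net peak is typically flagged `no_deflection` (real cells show
a small hump); and the Kv11 midpoint sits more negative than typical ERG
measurements because it is calibrated jointly with Kv12 to reproduce the
tail-blend V½ contrast. Passing tests therefore demonstrate that the
*analysis* is correct under the stated model, not that the model captures
every feature of real recordings.

## Problem sizes and known limitations

The test and acceptance workloads use desk-scale sizes chosen for fast,
deterministic runs: 15+15-cell populations over 50 seeds for the contrast
rates, 200 fits for the Boltzmann recovery rate, 500 replicates for null
calibration, 1000-gene synthetic expression tables.

Two quantitative limits are worth knowing. First, the `(Rm/(Rm+Rs))²`
attenuation means 1%-level Cm recovery holds only when Rs is small relative
to Rm (the recovery grid uses Rs ≤ 3 MΩ at Rm ≥ 1 GΩ); at perforated-patch
Rs values the bias reaches several percent and is reported as-is. Second,
for additive noise σ = 0.05 on the 15-point activation grid, the
Cramér–Rao bound puts the V½ estimator's standard deviation at ≈1.2 mV, so
no estimator can land within 2 mV of truth in more than ≈90% of runs; the
fit attains that floor (tested), and recovery-rate figures should be read
against it.
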