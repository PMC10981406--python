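# Methods

## Signal model

### Cardiac velocity envelope

All cardiac-phase dependence derives from a single normalised envelope
e(t): a raised-cosine pulse of width `systolic_width` (default 50 ms)
centred `arrival_delay` (default 25 ms) after each R-wave, repeating with
the cardiac period (60000/heart-rate ms; default 364 bpm → 164.8 ms). It is
1 at the systolic peak and exactly 0 outside the pulse, encoding the
assumption that perivascular fluid is driven forward by the systolic pulse
wave with essentially no motion during diastole. The raised cosine was
chosen for smoothness and compact support; the true envelope shape in vivo
is unknown, and any unimodal pulse of similar width would serve.

### Flow attenuation

A PGSE pair imparts phase φ = γGδΔ·v to a spin with constant velocity
component v along the gradient. Encoding is **quasi-static at the gate
time**: the per-spin velocity scale is v_eff = v_peak · e(gate delay), held
constant over the 31 ms encoding window. A window-*mean* velocity was
considered and rejected: because the window extends 31 ms beyond the gate,
its mean peaks ≈(Δ+δ)/2 before the pulse arrival, which would shift the
measured delay-response maximum to the 10 ms gate — the gated protocol's
empirical behaviour (response maximal when the gate sits at the arrival
delay) and the calibration identity both require the gate-time convention.

For the default **uniform** within-voxel speed distribution on [0, v_eff]
the magnitude attenuation has the closed form |sin(a/2)/(a/2)|,
a = γGδΔ·v_eff, which serves as the independent oracle for the Monte-Carlo
path (spins drawn per profile; |⟨e^{iφ}⟩| over 20 000 spins by default).
Alternatives: `plug` (coherent — pure phase shift, no magnitude attenuation,
illustrating that magnitude MRI cannot see perfectly coherent flow) and
`parabolic` (speeds v_eff·(1−r²) with r sampled uniformly along a
diameter).

### Compartments

* **PVS tracts** — directional flow along the tract axis plus isotropic
  pseudo-diffusion d_free (default 0.002 mm²/s; the absolute baseline level
  is a free parameter of the generator, as only directional *differences*
  are anchored by printed values). A fraction `perp_pulsatile_gain`
  (default 0.3) of the pulsatile dispersion acts isotropically, giving the
  perpendicular direction its cardiac dependence; being isotropic it cancels
  exactly in ΔD*.
* **SAS / third ventricle** — purely isotropic pulsatile dispersion:
  ADC = 0.002 + amplitude·e(delay) mm²/s (amplitudes 0.003 and 0.002),
  cardiac-dependent but identical for both gradient axes — the control-region
  property.
* **Tissue** — fixed ADC 7×10⁻⁴ mm²/s and a low S0 (0.1 vs 1.0 for fluid):
  the long-TE protocol suppresses tissue signal; relaxation and the
  echo train are deliberately not modelled, only their outcome.
* **Rician noise** — two independent Gaussian channels; SNR (default 40)
  defined on the b0 PVS signal. Region signals are computed once per
  acquisition and broadcast to the region's voxels before noise, so ROI
  statistics are identical to voxelwise simulation at desk-scale cost.

### b-value

(γGδ)²(Δ−δ/3) for the stated gradients evaluates to 39.2 s/mm², not the
protocol's printed 43 (imaging-gradient cross terms presumably account for
the gap). The nominal 43 is used by default in both the forward exponent and
the inversion — self-consistent, so round trips are exact — with
`use_nominal_b=False` switching both to the computed value.

## Calibration

`calibrate_v_peak` bisects the closed form so the noise-free systolic ΔD*
of one animal equals a target (tolerance well below 10⁻⁵ mm²/s); the first
phase-wrap null bounds the bracket. Preset flow amplitudes use
`calibrate_cohort_v_peak`, which solves the same identity for the
*cohort expectation* under log-normal between-animal variability
(Gauss–Hermite quadrature): the printed study values are cohort means and
the flow term is convex in v_peak (≈+5% at CV 0.2). Targets: 0.004 mm²/s
for the multidelay preset; 0.005 (Ang-II group) and 0.004 (vehicle group)
baselines for the hypertension preset. The Ang-II flow scaling
v_scale = v(0.003)/v(0.005) ≈ 0.78 maps the baseline cohort to the printed
post-injection mean — the study gives no wall-motion→flow transfer
function, so proportional scaling is an explicit assumption.

## Cohorts and conditions

Between-animal variability is log-normal (unit mean): CV 0.2 on v_peak, and
CV 0.09 on wall pulsation — the latter anchored to the printed baseline
wall-motion summary 0.22 ± 0.02 mm (capped at the flow CV so zero-variance
cohorts are fully degenerate; `CohortConfig.wall_cv` overrides). The Ang-II
condition is a static scaling: wall 0.17/0.22, flow ≈0.78, heart rate
364→353 bpm, and a −0.28 ms shift of the R-wave→peak-velocity interval
(40.64→40.36 ms, the printed post value); vehicle is the identity. No
pharmacokinetics, anaesthesia or breathing are modelled.

Measurement noise is the only within-animal stochasticity. All randomness
descends from one master seed through hierarchical integer seed paths
(experiment → group → animal → acquisition → stage), so runs are
byte-reproducible.

## Ultrasound arm

M-mode diameter = diastolic diameter (1 mm) + pulsation·e(t) at 1 kHz with
additive Gaussian noise (SD 1% of the pulsation amplitude); Doppler velocity
is a raised-cosine pulse (peak 500 mm/s over a 15% diastolic floor, noise 1%
of peak) peaking at the timing offset, sampled at 10 kHz for sub-ms timing
resolution. Extraction follows the protocol definitions literally: per-cycle
max−min diameter and per-cycle argmax-velocity minus R-wave time, cycles
delimited [Rᵢ, Rᵢ₊₁) with trailing partial cycles discarded, arithmetic
means across cycles and across the four 5-minute timepoints per period.

Two numerical consequences are documented rather than hidden: sampled traces
miss inter-sample envelope peaks (quadratic error ≤ (π·dt/width)²/2 of the
amplitude, ≈4×10⁻⁴ mm at 1 kHz), and max−min of a noisy trace is biased
upward by ≈3σ ≈ +0.008 mm at the default noise. Smoothing would remove the
bias but break the exact noise-free round trip, so the raw definition is
kept.

## Statistics

The signed-rank test is exact: zeros dropped, midranks for ties, the null
distribution of W⁺ computed by dynamic programming over sign assignments
(ranks doubled to integers), conditional on the observed tie pattern; the
one-tailed p includes the observed value, so n all-consistent differences
give p = 2⁻ⁿ. Valid and exact for the n ≤ 25 relevant here; a binomial sign
test is provided as a sensitivity alternative. Negative D* estimates
(noise pushing S above S0) are flagged but never clipped, keeping cohort
means unbiased. Bilateral combination averages D* values across tracts
(averaging signals first differs by <2% at the default noise, but the
D*-level average matches the per-direction protocol description).

## Experiment sizes and runtime

Defaults mirror the protocols: multidelay n = 10 × 11 delays × 3 volumes;
hypertension 2 groups × n = 6 × 2 periods × 7 repetitions at the 25 ms gate;
ultrasound Ang-II n = 6 / vehicle n = 3 × 2 periods × 4 timepoints of 2 s
traces. The rendering grid is 64×64×2 (30×30×2 mm FOV), the lower-resolution
protocol matrix; region-broadcast rendering makes each experiment run in a
few seconds on one CPU, and the acceptance script likewise.

## What the synthetic cohorts do and do not show

Passing recovery tests demonstrates that the estimation chain inverts the
generative model correctly at realistic noise and cohort sizes — not that
the generative model is the true physiology. Real data add partial-volume
mixing, imperfect tract/axis alignment, motion and ghosting, breathing,
heart-rate variability, T2/echo-train effects and manual-ROI variability,
none of which are simulated. The perpendicular direction's cardiac
dependence is modelled as isotropic dispersion (`perp_pulsatile_gain`);
whether it is dispersion or partial misalignment in vivo is unresolved.
Bulk flow and dispersion are not distinguishable by the measurement and are
not distinguished by the model. With between-animal CV 0.2 at n = 6, cohort
means legitimately wander ±15–20% between seeds; tolerance choices in the
test suite derive from this sampling error, not from the printed precision
alone.
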