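# Methods

## The phantom model

The simulator is a single-pass, two-compartment description of the perfusion
flow phantom:

* **Input chamber** (volume V_in = 15.7 ml, the blood-pool surrogate): a
  well-mixed compartment flushed at the pump flow F = Q_pump. With bolus
  delivery rate b(t) (MBq/s) and decay constant λ = ln2 / 122.24 s⁻¹,

      dC_in/dt = b(t)/V_in − (F/V_in + λ) C_in .

  No explicit dispersion term is modelled between the injection port and the
  chamber; the kinetic delay parameter absorbs transit time, and the chamber
  time constant V_in/F (≈ 3.8–6.3 s over the protocol's pump range) already
  low-pass-filters the bolus.

* **Exchange cylinder** (V_cyl = 160 ml, the myocardium surrogate): a
  one-tissue compartment fed by the chamber concentration delayed by Δ
  seconds, with uptake rate q_in and washout q_out (min⁻¹). Tracer decays
  during the Δ-second transit, so the decay-corrected sampled curves obey
  exactly the decay-free convolution model the fitter uses.

* **Measured tissue signal**: the cylinder concentration plus a spill-over
  term ISF·C_in(t−Δ) representing the perforated tube running through the
  tissue VOI. Two spill-over conventions are implemented and switchable
  everywhere (`spillover_mode`): `additive` (default), where the convolution
  term is not rescaled, and `scaled`, where it carries a factor (1 − ISF).
  The additive form is the package default because it matches the verbal
  definition of ISF as an added input-signal fraction; results for small ISF
  differ negligibly between the two.

Recirculation through the exterior container is neglected (single pass): the
scan is 280 s, the exterior volume is large, and the assumption makes
activity mass balance exactly testable — with λ = 0, injected activity equals
chamber + cylinder residuals + in-transit activity + cumulative outflow
(verified to ~10⁻⁸ relative; the tolerance asserted is 0.5%).

All solutions use an exact per-segment exponential convolution for
piecewise-linear inputs (`_conv.expconv_pl`), so simulator and forward model
share one numerical primitive; an independent stiff ODE integration
(`scipy.solve_ivp`, LSODA) agrees with the simulator to <0.1% of peak and is
kept as a test oracle only.

## Synthetic-data defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| requested activity | 500 MBq | the measurement protocol's request per injection |
| dispense tolerance | ±15% | injector vendor specification |
| bolus shape | gamma-variate, onset 2 s, α = 2, β = 2.5 s | peaks ~5 s after onset with ~10 s width, the scale of automated radiowater injector profiles; the true injector curves are only known graphically, so no fidelity beyond peak position/width is claimed |
| frame schedule | 14×5 s, 3×10 s, 3×20 s, 4×30 s | the clinical dynamic perfusion protocol (280 s, scan start = injection = t 0) |
| half-life | 122.24 s | ¹⁵O physical constant |
| pump/constriction grid | 150/200/250 ml/min × 20/40/60/80% | the 12 protocol settings; Q_ref = calibration × mean(pre, post) Q_cyl readings, and the ideal ground truth is q_in = q_out = Q_ref/V_cyl |
| noise model | Gaussian, SD = s·√(value/(duration·decay factor)) | the standard dynamic-PET frame-variance shape: counts grow with duration and fall as activity decays, so decay-corrected late frames are noisiest |
| noise scale s | 2.5 | calibrated so the relative SD at the tissue-curve peak is ≈3% (2–4% across the 12 settings). The anchor is the tissue curve because the phantom's VOIs are very large (the exchange cylinder is 160 ml), which makes real phantom TACs smooth; anchoring the same 3% at the much higher input peak would imply 13–18% per-frame tissue noise, which is not representative of the experiment this generator emulates. |

What the generator does **not** emulate: reconstruction (resolution,
partial-volume, scatter/randoms corrections and their temporal instability),
recirculation, flow-meter reading errors, or between-session setup drift.
Passing simulation tests therefore demonstrates correctness and
identifiability of the analysis chain, not scanner-level reproducibility —
the packaged study tables carry the empirical answer to the latter.

## Fitting

* Both TACs must be decay-corrected (correction uses the exact
  duration-weighted frame decay factor; apply/remove are exact inverses and
  double application is refused).
* The model predicts decay-corrected frame values as **decay-weighted** frame
  averages of the model curve: a decay-corrected frame value is the average
  of the decaying signal divided by the mean decay factor, which weights the
  early part of each frame more. Ignoring this is a ≈0.3% bias at high flows;
  modelling it (the half-life is a known constant) removes it.
* The continuous input is reconstructed from its 24 frame values by a
  bolus-like parametric base (gamma-variate ⊗ single-exponential chamber
  washout, 4 shape parameters fitted to the frame values) refined by
  multiplicative corrections until its decay-weighted frame averages
  reproduce the measured values; a PCHIP-through-midpoints base replaces the
  parametric one automatically whenever it explains the frames better (e.g.
  non-bolus-like curves). The parametric family coincides with the
  simulator's generative family, so noiseless in-family recovery is
  essentially exact; for out-of-family inputs the refinement still enforces
  frame-average consistency.
* Optimization: delay grid 0–30 s in 1 s steps; at each delay the problem is
  separable (model linear in q_in and ISF for fixed q_out), solved by a
  bounded 1-D search over q_out with an exact bounded 2-variable linear
  solve; the best grid point seeds a joint bounded `least_squares` polish of
  (q_in, q_out, ISF, Δ). Bounds: rates ∈ [0, 10] min⁻¹, ISF ∈ [0, 1]. Cost
  tolerance 1e-10, at most 2000 evaluations. The procedure is deterministic;
  non-convergence is returned in the `converged` flag, never discarded.
* Weights: inverse-variance weights from the dynamic-PET variance model
  (var ∝ value/(duration·decay factor²) for decay-corrected data, evaluated
  on the observed tissue values with a 5%-of-peak floor) are the default;
  plain duration weights are available (`weights="duration"`). Duration-only
  weighting over-weights the noise-amplified late frames and roughly
  quadruples the Monte-Carlo spread of recovered flows, which is why it is
  not the default.
* Degenerate inputs: an all-zero tissue curve fits q_in ≈ 0 and is flagged
  `low_signal`; mismatched schedules or missing decay correction raise.

## Statistics conventions

* Flow-value error: 100·|Q − Q_ref|/Q_ref. Repeatability error:
  100·(retest − test)/test, absolute by default; the signed variant
  reproduces the injected-activity difference column.
* Summary SD is the sample SD (n − 1); this convention reproduces the
  published "±8.4" on the 12 Vision-600 Q_in errors.
* Bland–Altman: differences DMI-20 − Vision-600, limits of agreement at
  mean ± 1.96 SD, test and retest sessions pooled (24 pairs per quantity).
* Table-reproduction checks compare at each printed cell's precision (two
  activity-difference cells are printed at 1 decimal, the rest at 2).
  Summary means recomputed from the *rounded printed* flow table cannot land
  exactly on summary values the authors computed from unrounded data;
  propagation of ±0.5 ml/min rounding puts them within ~0.25 of the printed
  means, and the checks use a documented ±0.5 tolerance (pp or ml/min).
  The per-measurement flow-value errors against Q_ref are exercised as
  properties only: the flow-meter calibration look-up table is not published,
  so Q_ref itself is not exactly recomputable.

## Known limitations

* The spill-over algebra of the original phantom software is not public;
  both plausible conventions are implemented, but only their shared behaviour
  at small ISF is validated.
* The bolus shape parameters are a graphical approximation; bolus-shape
  sensitivity of the fits is not part of the acceptance surface.
* Volume rendering writes uniform VOIs (no resolution or partial-volume
  effects) and stays in plain arrays; NIfTI export is intentionally out of
  scope.
* Problem sizes used by the shipped checks — 36 noiseless fits over the
  protocol flow range, 50 noisy replicate scans, 0.01 s oracle grids — were
  chosen as desk-scale settings that keep the full suite in the tens of
  seconds while leaving all conclusions unchanged at larger sizes.
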