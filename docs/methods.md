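# Methods

This note documents the models implemented in `calbold`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter when comparing results.

## Signal model and calibration regression

The BOLD-relevant tissue relaxation rate is modelled as linear in venous
deoxyhaemoglobin content (static dephasing regime, appropriate at high
field):

    R2* = k·V·Q + R2,0*,      k = (4/3)·π·Δχ·[Hb_tot]·B0,

with `V` the venous blood volume fraction, `Q = 1 − Yv` the venous dHb
fraction and `R2,0*` the rate of tissue with fully oxygenated vessels. At
hyperoxia level `q_h` (relative change in `Q`), rest and task states obey

    ΔR2*_rest(x) = k·V0·Q0·x − k·V0·Q0,
    ΔR2*_act(x)  = k·(V0+ΔV_act)·Q0·x + k·(V0+ΔV_act)·Q0·q_act − k·V0·Q0,

against the abscissa `x = 1 + q_h`, both measured relative to the normoxic
resting baseline. Two unweighted OLS lines (one point per usable trial per
condition) give `M = 100·TE·slope_rest`, `M′ = 100·TE·slope_act`,
`rvCBV = M′/M − 1` and `q_act = (intercept_act − intercept_rest)/slope_act`.

**Why the abscissa is `1 + q_h`, not `q_h`.** The rest/active intercept gap
equals `k·(V0+ΔV_act)·Q0·q_act` only at `x = 0`. Fitting against `q_h` and
differencing intercepts at `q_h = 0` would add an `(M′ − M)`-proportional
term to the gap and bias `q_act` by `rvCBV/(1+rvCBV)`; a unit test pins
this identity.

`k` never needs a value on the inverse path — it cancels in both ratios —
and exists in the code only so the simulator can generate forward data.
`β` is fixed at 1; supra-linear low-field variants are out of scope.

Standard errors come from the per-line OLS covariances with first-order
(delta-method) propagation for the slope ratio and the intercept-gap
quotient; the Monte Carlo module is the authoritative precision estimate.

**Baseline-OEF sensitivity.** Rescaling all `q_h` by a constant leaves both
slopes equally scaled, so rvCBV is exactly invariant to the assumed `Q0`.
For `q_act`, `rescale_q_act` applies the first-order propagation
`q_act → q_act·Q0_assumed/Q0_measured`, the convention used for
subject-level reporting. The exact refit with rescaled `q_h` differs by an
additional `(c−1)·rvCBV/(1+rvCBV)` term (`c` the `Q0` ratio); both
relations are unit-tested, and the exact form is what `run_calibration`
produces when given a measured `Q0`.

## From end-tidal oxygen to q_h

End-tidal PO2 is taken as arterial PaO2 — a stated model assumption
(sequential gas delivery makes the end-tidal-to-arterial gradient
negligible at this precision), not a configuration knob. The chain is:

1. Severinghaus dissociation curve at 310 K, pH 7.4:
   `SaO2 = (23400/(PaO2³ + 150·PaO2) + 1)⁻¹` (double precision, no lookup
   tables; temperature/pH corrections are out of scope).
2. Arterial content `CaO2 = φ·[Hb]·SaO2 + ε·PaO2` with φ = 1.34 ml(O2)/g,
   [Hb] = 15 g/dl, ε = 0.0031 ml/(dl·mm Hg).
3. Venous balance with level-independent extraction
   `OE = CaO2(baseline)·OEF`: `Yv = (CaO2(PaO2) − OE)/(φ·[Hb])`, neglecting
   dissolved O2 on the venous side (venous haemoglobin is far from
   saturation under normobaric hyperoxia).

The absolute change `ΔQ_h` between two PaO2 levels is independent of the
assumed OEF (extraction cancels); the relative change `q_h = ΔQ_h/Q0`
scales as `1/Q0`. Per gas block, PaO2 is the mean end-tidal O2 over the
block's final 2 minutes (steady-state window, configurable); the normoxic
reference pools all normoxia-block windows and normoxia blocks are assigned
`q_h = 0` by construction. A 110 → 440 mm Hg step at OEF 0.4 yields
ΔYv = 0.068, i.e. q_h = −0.169.

**Trial quality control.** The normocapnia reference is the mean end-tidal
CO2 over baseline timepoints; a trial is discarded when any CO2 sample in
its cycle (tap window plus following rest window) deviates by more than
1 mm Hg (configurable) — the rest window is included because both window
means feed the regression.

## Timecourse conditioning

Pipeline order: (motion-corrected input) → linear detrend → normalise →
trial means. Windows are half-open `[start, end)`; times in seconds.

* **Baseline** timepoints lie in a normoxia block, outside every trial's
  tap window and the 30 s that follow it.
* **Detrending** fits a line to baseline samples only and removes its slope
  about the baseline-time centroid, preserving the baseline mean that the
  subsequent normalisation divides by. Detrending is used instead of
  high-pass filtering because of the long paradigm cycle lengths.
* **Normalisation** divides by the baseline mean and reports % change.
* **Trial means**: the active window excludes the first 6 s of stimulation
  (haemodynamic rise) and the rest window is the OFF period immediately
  following the tap, excluding its first 6 s (post-stimulus decay). The
  6-s margins (≈2–3 TRs at TR 2.4 s) are a package convention — the window
  onsets are not prescribed by the estimator — and are configurable.
* **ASL**: tag and control streams (pair period 2·TR) are each linearly
  interpolated onto the single-image grid (edges clamped), subtracted
  control-minus-tag, normalised by the mean over the last half of every
  rest period, and averaged over ON windows. Because the effective temporal
  resolution is 2·TR, averaging windows end one TR before each ON/OFF
  transition: the interpolated frame straddling a transition mixes both
  states and would bias a boxcar response (without the retreat a
  programmed 58 % flow increase reads ≈54 %).

## Phase-ratio OEF

The extravascular field shift around a large vein is proportional to the
blood–tissue susceptibility difference, itself linear in `Q`:
`χ(Q) = Hct·[(1−Q)·Δχ_oxy + Q·Δχ_deoxy]` with Δχ_oxy = −0.017×10⁻⁶,
Δχ_deoxy = +0.247×10⁻⁶ (cgs), treating plasma and tissue as water. The
spatial pattern is identical at both gas states, so the no-intercept
least-squares ratio `a = Σφ_n·φ_h/Σφ_n²` along a line profile equals the
susceptibility ratio regardless of vessel geometry, tilt, B0 or TE
(asserted across randomised geometries). Inverting the linear model:

    Q0 = ΔQ_h/(a − 1) − Δχ_oxy/(Δχ_deoxy − Δχ_oxy),

with haematocrit cancelling. `∂Q0/∂a = −ΔQ_h/(a−1)² > 0`: a ratio closer
to 1 (weaker hyperoxia contrast) implies a larger baseline dHb fraction.
The published grouping of this inversion is typographically ambiguous; the
implemented form is derived from the linear susceptibility model and
validated by a forward/inverse round trip over Q0 ∈ [0.2, 0.6],
ΔQ_h ∈ [−0.12, −0.02] (<1 % error).

**Homodyne filter.** Background phase is removed by dividing the complex
image by its Gaussian-smoothed version (FWHM 4 mm). The filter is linear in
phase only in the small-phase regime, and it removes background a
thousandfold in power only when the background is smooth at the
field-of-view scale (the physically motivated case: the global shift from
oxygen accumulating in the frontal sinus and nasal cavity). The documented
tolerance — filtered ratio within 1 % of truth — holds for 1-rad
backgrounds at roughly 4× the dipole footprint (~50 mm) with the fit
restricted to ±8 mm of the vessel; structure near the 4-mm kernel scale is
only partially removed and degrades the ratio. Double filtering changes
the fitted ratio by <0.5 %.

**Synthetic vessel fixture.** An infinite cylinder at tilt θ to B0:
extravascular `ΔB/B0 = 2π·Δχ_cgs·sin²θ·(r_v/r)²·cos 2φ`, intravascular
`2π·Δχ_cgs·(cos²θ − 1/3)`, phase `= γ·B0·TE·ΔB/B0`; the magnitude map is
bright inside the vessel so an intensity threshold (default: 98th
percentile of the normoxia magnitude) flags intravascular samples. Fixture
tests use TE = 2.5 ms so phases stay below π: at 7 T/25 ms near-vessel
phase reaches ~10 rad and must be spatially unwrapped upstream — spatial
unwrapping is an input requirement, not implemented (temporal unwrapping by
nearest-2π tracking is provided).

## Susceptibility error budget

All susceptibilities are carried in units of 10⁻⁶ (cgs). The dissolved-O2
contribution is `χ_v = χ_m(O2)/(V_m·10³)·(ε·PaO2/100)` — the pure-gas
volume susceptibility (χ_m = +3415×10⁻⁶ cm³/mol, V_m = 24.5 L/mol)
weighted by the dissolved-gas volume fraction; the `/100` is the explicit
per-decilitre unit bridge for ε and is unit-tested. Representative values:
0.0005×10⁻⁶ at 110 mm Hg, 0.0022×10⁻⁶ at 500 mm Hg; an arterial
saturation gain of 0.017 changes blood susceptibility by −0.0018×10⁻⁶
(Hct 0.4); changing breathing gas from 21 % to 60 % O2 changes air
susceptibility by 0.0546×10⁻⁶ (computed; commonly quoted as 0.054).

## Simulator and Monte Carlo

The generator emulates the study conditions: Paradigm A — 3 min normoxia /
3 min hyperoxia repeated twice plus a final task-free 3 min normoxia
(15 min), with two 30 s ON/30 s OFF trials in the last two minutes of each
of the first four blocks (8 trials, 4 per gas condition); Paradigm B —
2 min normoxia then two repeats of (2 min hyperoxia + 4 min normoxia) with
30 s ON/60 s OFF trials every 90 s, alternate trials falling at gas
transitions and marked unusable (4 usable, 2 per condition; rest windows
clipped at block ends so they never straddle a transition). Sampling at
TR = 2.4 s, TE = 25 ms.

The default ground truth is the group-mean operating point: M = 36 %,
M′ = 48 % (k = 1200 s⁻¹, V0 = 0.03, ΔV_act = 0.01, Q0 = 0.4 — only the
products matter), q_act = −0.39, hyperoxia q_h = −0.17 (ΔYv = 0.068 at
Q0 = 0.4), tSNR = 161. This is a reconstruction of the conditions under
which the estimator's precision is quoted, not a fit to any dataset.

The signal mapping is **linear** in the relaxation change,
`S = S0·(1 − TE·ΔR2*)`, the exact inverse of the `%BOLD → ΔR2*`
conversion used on the analysis side, so the noiseless pipeline recovers
the truth to machine precision and noise enters symmetrically. An
exponential mapping `S0·exp(−TE·ΔR2*)` is available
(`nonlinearity="exponential"`) to quantify the linearisation error of the
conversion (~3 % of the response at these amplitudes). Noise is Gaussian
on magnitude with SD = S0/tSNR (high-SNR regime; no Rician option, no
physiological-noise harmonics). Responses are ideal boxcars: the estimator
averages steady-state plateaus, so haemodynamic response shape is
irrelevant to the means given the 6-s window margins; an exponential gas
transition (`transition_tau`) can stress the window choices. Optional
linear drift is multiplicative; additive detrending then leaves a small
residual bias (<0.02 in rvCBV at 0.5 %/min), which is tested.

Replicates use counter-based sub-seeds (`default_rng([seed, rep])`), so
the set of replicates is order-independent and every output is bit-exact
reproducible from `(config, seed)`. At the default operating point,
10,000 replicates give SD(rvCBV) ≈ 3.8 % and SD(q_act) ≈ 1.8 %, with mean
bias below 0.05 of one SD; SD scales as 1/tSNR (log–log slope −1). The
bias criterion used in testing is |bias| < 0.2·SD — bias negligible
relative to single-estimate precision — rather than a z-test, which at
10⁴ replicates would resolve biases two orders below any practical
relevance.

**What passing tests do and do not show.** The generator shares the
analysis pipeline's window conventions and has no haemodynamic transients,
motion, physiological noise or spatial structure beyond the two-region
phantom; recovery and precision results therefore validate the estimator's
statistical behaviour under the stated model, not robustness to real-data
artefacts (motion correction and activation-mask definition are inputs to
this package, not part of it).

## Degenerate inputs and numerical conventions

* Pressures in mm Hg, times in seconds, saturations as fractions
  (percent only in human-facing output; machine-facing JSON carries
  explicit `units` keys).
* Calibration requires ≥2 distinct q_h levels (rank check) and a positive
  rest slope; voxels with zero temporal variance are flagged NaN in maps.
* The phase-ratio fit requires ≥3 included samples and non-degenerate
  normoxia phase power; `q0_from_ratio` rejects `a = 1`, `ΔQ_h ≥ 0` and
  any inferred Q0 outside (0, 1) with diagnostics.
* OLS standard errors are NaN at zero residual degrees of freedom (exactly
  two points per line).

## Known limitations

* The two in-vivo mask-dependent group results (M, rvCBV, baseline
  hyperoxia BOLD) require subject data and are used only as simulator
  ground truth, not as machine-checked outputs.
* 1-D line profiles only; 2-D neighbourhood phase fitting, quantitative
  susceptibility mapping and T2-based oximetry are out of scope.
* No hypercapnia-based calibration and no CBV/CBF coupling utilities — the
  method exists to avoid the latter.
* GLM activation mapping, motion correction and spatial phase unwrapping
  are upstream steps; their outputs (masks, corrected series, unwrapped
  phase) are inputs here.
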