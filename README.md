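# calbold

Calibrated BOLD fMRI from a task repeated at **normoxia and hyperoxia**:
estimate the relative changes in venous cerebral blood volume (rvCBV), venous
deoxyhaemoglobin fraction (q_act) and oxygen metabolism (rCMRO2) produced by
a stimulus, **without assuming a CBV/CBF coupling law** (no Grubb exponent).
The package is aimed at quantitative-fMRI researchers working with
respiratory-challenge data: it takes end-tidal O2/CO2 traces, ROI (or
voxelwise) BOLD timecourses, interleaved ASL tag/control series and paradigm
timing, and returns the calibration parameters and physiological changes,
together with a phase-ratio estimator of baseline oxygen extraction fraction
(OEF) and a forward simulator for precision analysis.

## The model

With a linear (static-dephasing, β = 1) signal model the tissue relaxation
rate is

    R2* = k·V·Q + R2,0*

where `V` is the venous blood volume fraction and `Q = 1 − Yv` the venous
deoxyhaemoglobin fraction. Isocapnic hyperoxia multiplies the resting
`Q0` by `(1 + q_h)`; the task adds `q_act` and changes the volume by
`ΔV_act`. Measuring the rest and active ΔR2* (from %BOLD via
`ΔR2* ≈ −%BOLD/(100·TE)`) at two or more hyperoxia levels and regressing
against the abscissa `x = 1 + q_h` gives two lines whose

* slopes are `M = 100·TE·k·V0·Q0` and `M′ = 100·TE·k·(V0+ΔV_act)·Q0` (% units),
* slope ratio gives `rvCBV = M′/M − 1`,
* intercept gap over the active slope gives `q_act`.

`q_h` itself comes from the measured end-tidal O2 trace through the
Severinghaus dissociation curve, the arterial O2 content
`CaO2 = φ·[Hb]·SaO2 + ε·PaO2`, and a venous balance with level-independent
oxygen extraction. Fick's principle then converts an ASL-measured flow
change into metabolism:

    1 + rCMRO2 = (1 + q_act)·(1 + rCBF).

Baseline OEF (= `Q0`) enters only as the scale of `q_h`: it can be assumed
(0.4) or measured from the hyperoxia:normoxia ratio `a` of the extravascular
phase around a large vein, which inverts to
`Q0 = ΔQ_h/(a−1) − Δχ_oxy/(Δχ_deoxy−Δχ_oxy)`.

## Worked example

Simulate a 15-minute dual-gas run (motor trials at both gas levels,
temporal SNR 161) and calibrate it:

```sh
$ calbold simulate --out-dir demo --seed 7
wrote simulation bundle to demo
$ calbold calibrate --bold demo/bold.tsv --endtidal demo/endtidal.tsv \
      --paradigm demo/paradigm.json --out demo/fit.json
M = 35.8 %  M' = 48.2 %  rvCBV = 34.6 %  q_act = -39.7 %
```

The ground truth of the bundle (`demo/truth.json`) is M = 36 %, M′ = 48 %,
rvCBV = 33.3 %, q_act = −39 %: the single noisy run lands within the
Monte Carlo precision below. `M` is the BOLD signal change that would be
observed if the venous blood became fully oxygenated; `rvCBV` the fractional
venous blood volume increase on activation; `q_act` the fractional drop in
venous deoxyhaemoglobin.

Combining a measured flow response with `q_act` (here the values of one
subject-level analysis: rCBF = 58 %, q_act = −29 %):

```sh
$ calbold cmro2 --q-act -0.29 --rcbf 0.58
rCMRO2 = 12.2 %
```

Other subcommands: `gas` (per-block q_h from an end-tidal trace),
`montecarlo` (estimator precision), `phase-oef` (OEF from a phase-profile
ratio; `--synthetic-q0` exercises the built-in vessel fixture),
`error-budget` (susceptibility contributions of dissolved O2, haemoglobin
saturation and breathing-gas changes), and `maps` (voxelwise NIfTI maps of
M, rvCBV and q_act). File formats are documented in `docs/formats.md`.

Monte Carlo precision at the default operating point (10,000 replicates,
tSNR 161, Paradigm A):

```sh
$ calbold montecarlo --n-reps 10000 --seed 20 --out mc.json
SD(rvCBV) = 3.82 %  SD(q_act) = 1.83 %  (0 failed fits)
```

with mean estimates within a small fraction of one SD of the truth.

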