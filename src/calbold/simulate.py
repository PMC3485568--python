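"""Forward simulation with known ground truth, and Monte Carlo precision.

The generator emulates the study conditions: a motor task repeated at
normoxia and isocapnic hyperoxia (end-tidal O2 driven from ~110 toward
500 mm Hg), BOLD sampled at TR = 2.4 s and TE = 25 ms at 7 T, with
temporal SNR 161 in the activated-ROI average.

Paradigm A: 3 min normoxia, 3 min hyperoxia, repeated twice, plus a final
task-free 3 min normoxia recovery (15 min total). The last two minutes of
each of the first four gas blocks carry two 30 s ON / 30 s OFF trials —
8 trials, 4 per gas condition, none touching a gas transition.

Paradigm B: 2 min normoxia then two repeats of (2 min hyperoxia + 4 min
normoxia); trials of 30 s ON / 60 s OFF start every 90 s from t = 90 s.
Alternate trials fall at a respiratory transition and are marked unusable,
leaving 4 usable trials (2 per condition).

The BOLD mapping is linear in the relaxation change,
S(t) = S0 * (1 - TE * dR2*(t)) * drift(t) + noise, the exact inverse of the
dR2* ~ -%BOLD/(100 TE) conversion used on the analysis side, so the
noiseless pipeline recovers the truth to machine precision and noise
perturbs it symmetrically; an exponential mapping S0 * exp(-TE * dR2*) is
available to probe the linearisation error. Noise is Gaussian on magnitude
(high-SNR regime) with SD = S0 / tsnr.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .calibration import (
    SignalModelParams,
    fit_calibration,
    forward_r2s,
    points_from_summaries,
)
from .gas import EndTidalTrace
from .preprocess import (
    GasBlock,
    Paradigm,
    RoiTimecourse,
    Trial,
    baseline_mask,
    detrend_linear,
    normalise_to_baseline,
    trial_summaries,
)

__all__ = [
    "SimulationConfig",
    "PrecisionReport",
    "make_paradigm",
    "synth_endtidal",
    "simulate_bold",
    "synth_asl",
    "monte_carlo",
]


def make_paradigm(variant: str = "A", tr: float = 2.4) -> Paradigm:
    """Build the gas-block and motor-trial timing tables for a variant."""
    if variant == "A":
        blocks = [
            GasBlock("normoxia", 0.0, 180.0),
            GasBlock("hyperoxia", 180.0, 360.0),
            GasBlock("normoxia", 360.0, 540.0),
            GasBlock("hyperoxia", 540.0, 720.0),
            GasBlock("normoxia", 720.0, 900.0),
        ]
        trials = []
        for b in blocks[:4]:  # final normoxia block is task-free recovery
            for k in (0, 1):
                onset = b.start + 60.0 + 60.0 * k
                trials.append(Trial(onset=onset, duration=30.0, off_end=onset + 60.0))
        return Paradigm(blocks=blocks, trials=trials, variant="A", tr=tr)
    if variant == "B":
        blocks = [
            GasBlock("normoxia", 0.0, 120.0),
            GasBlock("hyperoxia", 120.0, 240.0),
            GasBlock("normoxia", 240.0, 480.0),
            GasBlock("hyperoxia", 480.0, 600.0),
            GasBlock("normoxia", 600.0, 840.0),
        ]
        transitions = [b.start for b in blocks[1:]]
        trials = []
        for k in range(8):
            onset = 90.0 + 90.0 * k
            on_end = onset + 30.0
            # alternate trials fall at a respiratory transition: unusable
            # when one occurs within the tap window, the settling 30 s
            # before it, or the first 30 s of the following rest
            usable = not any(
                onset - 30.0 <= tt < on_end + 30.0 for tt in transitions
            )
            # rest window never crosses into the next gas state
            block_end = next(b.end for b in blocks if b.start <= onset < b.end)
            trials.append(
                Trial(
                    onset=onset,
                    duration=30.0,
                    off_end=min(on_end + 60.0, block_end),
                    usable=usable,
                )
            )
        return Paradigm(blocks=blocks, trials=trials, variant="B", tr=tr)
    raise ValueError(f"unknown paradigm variant {variant!r}")


def _block_value(paradigm: Paradigm, t: np.ndarray, by_label: dict, tau: float) -> np.ndarray:
    """Piecewise block value over time with optional exponential transitions."""
    out = np.empty_like(t)
    prev_val = by_label[paradigm.blocks[0].label]
    for b in paradigm.blocks:
        sel = (t >= b.start) & (t < b.end)
        target = by_label[b.label]
        if tau > 0:
            out[sel] = target + (prev_val - target) * np.exp(-(t[sel] - b.start) / tau)
            prev_val = target + (prev_val - target) * np.exp(-(b.end - b.start) / tau)
        else:
            out[sel] = target
            prev_val = target
    return out


def synth_endtidal(
    paradigm: Paradigm,
    baseline_po2: float = 110.0,
    target_po2: float = 500.0,
    transition_tau: float = 15.0,
    baseline_co2: float = 40.0,
    co2_overshoot: Optional[tuple[float, float, float]] = None,
    dt: float = 1.0,
) -> EndTidalTrace:
    """Synthetic end-tidal O2/CO2 traces locked to the gas paradigm.

    O2 approaches each block's target exponentially with time constant
    `transition_tau` (0 gives ideal steps). CO2 sits at `baseline_co2`,
    optionally with a transient overshoot (amplitude mm Hg, start s,
    duration s) emulating the brief CO2 excursions seen at hyperoxia
    transitions.
    """
    t = np.arange(0.0, paradigm.duration, dt)
    po2 = _block_value(
        paradigm, t, {"normoxia": baseline_po2, "hyperoxia": target_po2}, transition_tau
    )
    co2 = np.full_like(t, baseline_co2)
    if co2_overshoot is not None:
        amp, start, dur = co2_overshoot
        co2 = co2 + amp * ((t >= start) & (t < start + dur))
    return EndTidalTrace(times=t, peto2=po2, petco2=co2)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise description for the forward BOLD simulator.

    The default truth reconstructs the group-mean operating point: M = 36 %,
    M' = 48 % (via k = 1200 s^-1, V0 = 0.03, dV_act = 0.01, Q0 = 0.4),
    q_act = -0.39, hyperoxia q_h = -0.17 (venous saturation increase 0.068
    at Q0 = 0.4), Paradigm A at TR 2.4 s / TE 25 ms, tSNR 161.
    """

    variant: str = "A"
    tr: float = 2.4
    params: SignalModelParams = field(default_factory=SignalModelParams)
    qh_hyperoxia: float = -0.17
    tsnr: float = 161.0
    n_reps: int = 10_000
    seed: int = 0
    drift_pct_per_min: float = 0.0
    baseline_signal: float = 100.0
    transition_tau: float = 0.0
    nonlinearity: str = "linear"  # or "exponential"

    def __post_init__(self) -> None:
        if self.tsnr <= 0:
            raise ValueError("tsnr must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.nonlinearity not in ("linear", "exponential"):
            raise ValueError("nonlinearity must be 'linear' or 'exponential'")

    def paradigm(self) -> Paradigm:
        return make_paradigm(self.variant, self.tr)

    def qh_by_block(self, paradigm: Optional[Paradigm] = None) -> np.ndarray:
        paradigm = paradigm or self.paradigm()
        return np.array(
            [0.0 if b.label == "normoxia" else self.qh_hyperoxia for b in paradigm.blocks]
        )


@dataclass(frozen=True)
class PrecisionReport:
    """Monte Carlo summary of estimator precision and bias."""

    truth: dict
    mean: dict
    sd: dict
    bias: dict
    n_reps: int
    n_failed: int
    unstable: bool  # flagged when >10 % of fits failed

    def to_dict(self) -> dict:
        return {
            "truth": self.truth,
            "mean": self.mean,
            "sd": self.sd,
            "bias": self.bias,
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
            "unstable": self.unstable,
        }


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    # counter-based sub-streams: replicate order does not matter
    return np.random.default_rng([seed, rep])


def simulate_bold(
    config: SimulationConfig,
    rep_seed: int = 0,
    paradigm: Optional[Paradigm] = None,
) -> RoiTimecourse:
    """One synthetic ROI BOLD timecourse with the configured ground truth.

    dR2*(t) is the forward signal model evaluated with the block's q_h and
    the trial boxcar, relative to the normoxic resting baseline; the signal
    mapping, drift and noise are described in the module docstring. A fixed
    (config.seed, rep_seed) pair gives bit-identical output.
    """
    p = config.params
    paradigm = paradigm or config.paradigm()
    t = paradigm.sample_times()
    qh_t = _block_value(
        paradigm,
        t,
        {"normoxia": 0.0, "hyperoxia": config.qh_hyperoxia},
        config.transition_tau,
    )
    active = np.zeros(t.shape, dtype=bool)
    for tr_ in paradigm.trials:
        active |= (t >= tr_.onset) & (t < tr_.on_end)

    r2_base = forward_r2s(p, 0.0, False)
    scale = p.k * p.q0
    dr2s = np.where(
        active,
        scale * (p.v0 + p.dv_act) * (1.0 + qh_t + p.q_act),
        scale * p.v0 * (1.0 + qh_t),
    ) + p.r2_0 - r2_base

    if config.nonlinearity == "linear":
        s = config.baseline_signal * (1.0 - p.te * dr2s)
    else:
        s = config.baseline_signal * np.exp(-p.te * dr2s)
    if config.drift_pct_per_min:
        s = s * (1.0 + config.drift_pct_per_min / 100.0 * t / 60.0)
    if np.isfinite(config.tsnr):
        rng = _rep_rng(config.seed, rep_seed)
        s = s + rng.normal(0.0, config.baseline_signal / config.tsnr, size=t.shape)
    return RoiTimecourse(times=t, values=s)


def synth_asl(
    paradigm: Paradigm,
    rcbf: float,
    tr: float = 3.0,
    static: float = 100.0,
    perfusion: float = 1.0,
    tsnr: float = np.inf,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Interleaved tag/control streams with a boxcar flow increase.

    The perfusion-weighted difference is `perfusion` at rest and
    `perfusion * (1 + rcbf)` during trial ON windows; tag images at
    t = 0, 2 TR, ... and controls at t = TR, 3 TR, ....
    """
    n = int(np.floor(paradigm.duration / (2.0 * tr)))
    t_tag = 2.0 * tr * np.arange(n)
    t_ctl = tr + 2.0 * tr * np.arange(n)

    def flow(tvec: np.ndarray) -> np.ndarray:
        on = np.zeros(tvec.shape, dtype=bool)
        for tr_ in paradigm.trials:
            on |= (tvec >= tr_.onset) & (tvec < tr_.on_end)
        return perfusion * (1.0 + rcbf * on)

    tag = static - 0.5 * flow(t_tag)
    control = static + 0.5 * flow(t_ctl)
    if np.isfinite(tsnr):
        rng = np.random.default_rng(seed)
        tag = tag + rng.normal(0.0, static / tsnr, n)
        control = control + rng.normal(0.0, static / tsnr, n)
    return tag, control


def run_replicate(config: SimulationConfig, rep_seed: int, paradigm=None, base=None):
    """simulate -> detrend -> normalise -> trial means -> calibration fit."""
    paradigm = paradigm or config.paradigm()
    tc = simulate_bold(config, rep_seed, paradigm)
    if base is not None:
        tc = RoiTimecourse(tc.times, tc.values, base)
    tc = normalise_to_baseline(detrend_linear(tc, paradigm), paradigm)
    summ = trial_summaries(tc, paradigm)
    pts = points_from_summaries(summ, config.qh_by_block(paradigm), config.params.te)
    return fit_calibration(pts, config.params.te)


def monte_carlo(config: SimulationConfig) -> PrecisionReport:
    """Estimator precision over `config.n_reps` independent noise replicates.

    Each replicate runs the full analysis pipeline on a fresh simulated
    timecourse (independent counter-based sub-seed) and contributes its
    fitted M, M', rvCBV and q_act. The report carries the mean, SD and bias
    (mean minus truth) over successful fits; >10 % failures flag the run as
    unstable.
    """
    if config.n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a precision estimate")
    paradigm = config.paradigm()
    base = baseline_mask(paradigm, paradigm.sample_times())
    est = {k: [] for k in ("m", "m_prime", "rvcbv", "q_act")}
    n_failed = 0
    for rep in range(config.n_reps):
        try:
            fit = run_replicate(config, rep, paradigm, base)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        est["m"].append(fit.m)
        est["m_prime"].append(fit.m_prime)
        est["rvcbv"].append(fit.rvcbv)
        est["q_act"].append(fit.q_act)

    p = config.params
    truth = {
        "m": p.m_percent,
        "m_prime": p.m_prime_percent,
        "rvcbv": p.rvcbv,
        "q_act": p.q_act,
    }
    mean = {k: float(np.mean(v)) if v else float("nan") for k, v in est.items()}
    sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan") for k, v in est.items()}
    bias = {k: mean[k] - truth[k] for k in truth}
    return PrecisionReport(
        truth=truth,
        mean=mean,
        sd=sd,
        bias=bias,
        n_reps=config.n_reps,
        n_failed=n_failed,
        unstable=n_failed > 0.1 * config.n_reps,
    )
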