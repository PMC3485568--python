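"""Timecourse conditioning: baselines, detrending, normalisation, trial means, ASL.

The calibration regressions consume one (rest %, active %) pair per usable
motor trial, expressed against the normoxic resting baseline. This module
defines the paradigm structures and the deterministic pipeline that turns a
raw ROI timecourse into those pairs:

    baseline mask -> linear detrend (baseline-fitted) -> normalise to
    baseline -> per-trial window means

plus the tag/control interpolation-and-subtraction path that turns an
interleaved ASL acquisition into a relative CBF change.

Window conventions: time windows are half-open [start, end); sample i of a
series lives at times[i]. Active means exclude the first `on_margin` seconds
of stimulation (haemodynamic rise), rest means use the OFF period
immediately following the ON window excluding the first `rest_margin`
seconds (post-stimulus decay).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GasBlock",
    "Trial",
    "Paradigm",
    "RoiTimecourse",
    "TrialSummary",
    "baseline_mask",
    "detrend_linear",
    "normalise_to_baseline",
    "trial_summaries",
    "asl_rcbf",
]

POST_TRIAL_EXCLUSION_S = 30.0  # baseline excludes this long after each trial


@dataclass(frozen=True)
class GasBlock:
    label: str  # "normoxia" or "hyperoxia"
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in ("normoxia", "hyperoxia"):
            raise ValueError(f"unknown gas label {self.label!r}")
        if not self.end > self.start:
            raise ValueError("block end must exceed start")


@dataclass(frozen=True)
class Trial:
    """One motor trial: ON window [onset, onset+duration), rest until off_end."""

    onset: float
    duration: float
    off_end: float
    usable: bool = True

    @property
    def on_end(self) -> float:
        return self.onset + self.duration


@dataclass
class Paradigm:
    """Gas-block and motor-trial timing structure of one run."""

    blocks: list[GasBlock]
    trials: list[Trial]
    variant: str = "A"
    tr: float = 2.4

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        bs = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(bs, bs[1:]):
            if b.start < a.end:
                raise ValueError("gas blocks overlap")
        self.blocks = bs
        self.trials = sorted(self.trials, key=lambda t: t.onset)

    @property
    def duration(self) -> float:
        return self.blocks[-1].end

    def block_index_at(self, t: float) -> int:
        for i, b in enumerate(self.blocks):
            if b.start <= t < b.end:
                return i
        raise ValueError(f"time {t} falls outside every gas block")

    def gas_at(self, t: float) -> str:
        return self.blocks[self.block_index_at(t)].label

    def trial_condition(self, trial: Trial) -> str:
        """Gas condition of a trial, from the block containing its onset."""
        return self.gas_at(trial.onset)

    def sample_times(self) -> np.ndarray:
        """Acquisition grid 0, tr, 2*tr, ... covering the run."""
        n = int(np.floor(self.duration / self.tr + 1e-9))
        return np.arange(n) * self.tr


@dataclass
class RoiTimecourse:
    """ROI (or single-voxel) signal series with an optional baseline mask."""

    times: np.ndarray
    values: np.ndarray
    baseline: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=bool)
            if self.baseline.shape != self.times.shape:
                raise ValueError("baseline mask length mismatch")


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial window means (in % change vs normoxic baseline)."""

    trial_index: int
    condition: str  # "normoxia" | "hyperoxia"
    block_index: int
    rest_pct: float
    active_pct: float


def baseline_mask(paradigm: Paradigm, times: np.ndarray) -> np.ndarray:
    """True at resting-normoxia timepoints.

    A timepoint is baseline when it falls inside a normoxia block and is not
    within any trial cycle's tapping window nor the 30 s that follow it
    (signal still recovering from the previous finger tap).
    """
    t = np.asarray(times, dtype=float)
    mask = np.zeros(t.shape, dtype=bool)
    for b in paradigm.blocks:
        if b.label == "normoxia":
            mask |= (t >= b.start) & (t < b.end)
    for tr in paradigm.trials:
        mask &= ~((t >= tr.onset) & (t < tr.on_end + POST_TRIAL_EXCLUSION_S))
    return mask


def _ensure_baseline(tc: RoiTimecourse, paradigm: Optional[Paradigm]) -> np.ndarray:
    if tc.baseline is not None:
        return tc.baseline
    if paradigm is None:
        raise ValueError("timecourse has no baseline mask and no paradigm was given")
    return baseline_mask(paradigm, tc.times)


def detrend_linear(
    tc: RoiTimecourse, paradigm: Optional[Paradigm] = None
) -> RoiTimecourse:
    """Remove the linear drift fitted to baseline timepoints only.

    A straight line is fitted to the baseline samples and its slope is
    subtracted about the baseline-time centroid, so the baseline mean is
    preserved (the subsequent normalisation divides by it). Task and
    hyperoxia responses, living outside the baseline, pass through
    untouched apart from the drift removal.
    """
    base = _ensure_baseline(tc, paradigm)
    tb = tc.times[base]
    if tb.size < 2 or np.ptp(tb) == 0:
        raise ValueError("need >= 2 baseline timepoints with distinct times")
    slope, intercept = np.polyfit(tb, tc.values[base], 1)
    out = tc.values - slope * (tc.times - tb.mean())
    return RoiTimecourse(tc.times, out, base)


def normalise_to_baseline(
    tc: RoiTimecourse, paradigm: Optional[Paradigm] = None
) -> RoiTimecourse:
    """Convert to % signal change about the baseline mean.

    Divides by the mean over baseline timepoints and re-expresses as
    percent change, so the baseline reads 0 % and a hyperoxia plateau of
    +6.4 % reads 6.4.
    """
    base = _ensure_baseline(tc, paradigm)
    if not np.any(base):
        raise ValueError("empty baseline mask")
    mu = tc.values[base].mean()
    if mu <= 0:
        raise ValueError("baseline mean must be positive to normalise")
    return RoiTimecourse(tc.times, (tc.values / mu - 1.0) * 100.0, base)


def _window_mean(times: np.ndarray, values: np.ndarray, lo: float, hi: float) -> float:
    sel = (times >= lo) & (times < hi)
    if not np.any(sel):
        raise ValueError(f"no samples in window [{lo}, {hi})")
    return float(values[sel].mean())


def trial_summaries(
    tc: RoiTimecourse,
    paradigm: Paradigm,
    keep: Optional[Sequence[bool]] = None,
    on_margin: float = 6.0,
    rest_margin: float = 6.0,
) -> list[TrialSummary]:
    """Per-usable-trial rest/active % means versus the normoxic baseline.

    `tc` must already be in % change units (see `normalise_to_baseline`).
    `keep` carries the CO2 quality-control flags; trials marked unusable in
    the paradigm (e.g. those straddling a gas transition) are always
    skipped. Raises when a gas condition is left with no usable trial —
    the two-line calibration is then impossible.
    """
    if keep is None:
        keep = [True] * len(paradigm.trials)
    if len(keep) != len(paradigm.trials):
        raise ValueError("keep flags length mismatch")
    out: list[TrialSummary] = []
    for i, tr in enumerate(paradigm.trials):
        if not (tr.usable and keep[i]):
            continue
        active = _window_mean(tc.times, tc.values, tr.onset + on_margin, tr.on_end)
        rest = _window_mean(tc.times, tc.values, tr.on_end + rest_margin, tr.off_end)
        out.append(
            TrialSummary(
                trial_index=i,
                condition=paradigm.trial_condition(tr),
                block_index=paradigm.block_index_at(tr.onset),
                rest_pct=rest,
                active_pct=active,
            )
        )
    for cond in ("normoxia", "hyperoxia"):
        if any(b.label == cond for b in paradigm.blocks) and not any(
            s.condition == cond for s in out
        ):
            raise ValueError(f"no usable trials at {cond}: calibration impossible")
    return out


def asl_rcbf(
    tag: np.ndarray,
    control: np.ndarray,
    paradigm: Paradigm,
    tr: float,
    t0: float = 0.0,
    on_margin: float = 6.0,
    keep: Optional[Sequence[bool]] = None,
) -> float:
    """Relative CBF change from an interleaved tag/control ASL acquisition.

    Tag images are acquired at t0, t0+2*TR, ... and controls at t0+TR,
    t0+3*TR, ... (pair period 2*TR). Each stream is linearly interpolated
    onto the full single-image grid (edge samples clamped to the nearest
    value), then subtracted control-minus-tag to give a perfusion-weighted
    series at period TR. The series is normalised by the mean over the last
    half of every rest (OFF) period, and rCBF is the mean fractional change
    over the trials' ON windows.
    """
    tag = np.asarray(tag, dtype=float)
    control = np.asarray(control, dtype=float)
    if tag.shape != control.shape or tag.ndim != 1:
        raise ValueError("tag and control must be equal-length 1-D series")
    n = tag.size
    t_tag = t0 + 2.0 * tr * np.arange(n)
    t_ctl = t0 + tr + 2.0 * tr * np.arange(n)
    grid = t0 + tr * np.arange(2 * n)
    tag_i = np.interp(grid, t_tag, tag)  # np.interp clamps at the edges
    ctl_i = np.interp(grid, t_ctl, control)
    perf = ctl_i - tag_i

    if keep is None:
        keep = [True] * len(paradigm.trials)
    trials = [
        tr_ for i, tr_ in enumerate(paradigm.trials) if tr_.usable and keep[i]
    ]
    if not trials:
        raise ValueError("no usable trials for ASL averaging")

    # the effective temporal resolution is 2*TR: an interpolated frame
    # within one TR of a state transition mixes both states, so window
    # ends retreat by one TR
    rest_sel = np.zeros(grid.shape, dtype=bool)
    on_sel = np.zeros(grid.shape, dtype=bool)
    for tr_ in trials:
        mid = 0.5 * (tr_.on_end + tr_.off_end)
        rest_sel |= (grid >= mid) & (grid < tr_.off_end - tr)
        on_sel |= (grid >= tr_.onset + on_margin) & (grid < tr_.on_end - tr)
    if not np.any(rest_sel) or not np.any(on_sel):
        raise ValueError("empty rest or active ASL window")
    rest_mean = perf[rest_sel].mean()
    if rest_mean == 0:
        raise ValueError("zero resting perfusion signal; cannot normalise")
    return float(perf[on_sel].mean() / rest_mean - 1.0)
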