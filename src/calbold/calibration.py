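"""Two-condition calibrated-BOLD regression: M, M', rvCBV, q_act and rCMRO2.

The linear (static-dephasing, beta = 1) signal model writes the tissue
transverse relaxation rate as R2* = k * V * Q + R2,0*, with V the venous
blood volume fraction and Q the venous deoxyhaemoglobin fraction. Repeating
the same task at two or more hyperoxia levels q_h gives, against the
abscissa x = (1 + q_h),

    rest:   dR2*_rest(x) = k V0 Q0 * x          - k V0 Q0
    active: dR2*_act(x)  = k (V0+dV) Q0 * x + k (V0+dV) Q0 q_act - k V0 Q0

(both measured relative to the normoxic resting baseline). Two ordinary
least-squares lines then yield everything the method reports without any
CBV/CBF coupling assumption:

    M  = 100 * TE * slope_rest,   M' = 100 * TE * slope_act      (% units)
    rvCBV = M'/M - 1
    q_act = (intercept_act - intercept_rest) / slope_act

and Fick's principle converts q_act plus an ASL-measured rCBF into
1 + rCMRO2 = (1 + q_act)(1 + rCBF).

The abscissa is (1 + q_h), not q_h: the intercept difference equals
k (V0+dV) Q0 q_act only at x = 0; fitting against q_h and differencing at
q_h = 0 would add an (M' - M) term to the intercept gap.

k never needs a value on this inverse path — it cancels in both ratios —
and is exposed only so the simulator can generate forward data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SignalModelParams",
    "CalibrationPoint",
    "CalibrationFit",
    "CMRO2Result",
    "percent_bold_to_dr2s",
    "dr2s_to_percent_bold",
    "forward_r2s",
    "fit_calibration",
    "fick_rcmro2",
    "delta_y_act",
    "rescale_q_act",
    "points_from_summaries",
    "voxelwise_maps",
]


@dataclass(frozen=True)
class SignalModelParams:
    """Ground-truth parameters of the linear R2* signal model.

    v0: resting venous CBV fraction; dv_act: absolute vCBV change on
    activation; q0: resting dHb fraction (OEF); q_act: relative dHb change
    on activation; k: field/haemoglobin constant in s^-1 per (volume
    fraction * dHb fraction) — 4/3 pi dChi [Hb_tot] B0 in the static
    dephasing model, where B0 enters only through k; r2_0: relaxation rate
    of tissue with fully oxygenated vessels, s^-1; te: echo time, s.
    """

    v0: float = 0.03
    dv_act: float = 0.01
    q0: float = 0.4
    q_act: float = -0.39
    k: float = 1200.0
    r2_0: float = 20.0
    te: float = 0.025

    def __post_init__(self) -> None:
        if not 0.0 < self.v0 < 1.0:
            raise ValueError("v0 must lie in (0, 1)")
        if not 0.0 < self.v0 + self.dv_act < 1.0:
            raise ValueError("v0 + dv_act must lie in (0, 1)")
        if not 0.0 < self.q0 < 1.0:
            raise ValueError("q0 must lie in (0, 1)")
        if self.k <= 0 or self.te <= 0:
            raise ValueError("k and te must be positive")

    @property
    def m_percent(self) -> float:
        """Calibration parameter M implied by the truth, % signal units."""
        return 100.0 * self.te * self.k * self.v0 * self.q0

    @property
    def m_prime_percent(self) -> float:
        return 100.0 * self.te * self.k * (self.v0 + self.dv_act) * self.q0

    @property
    def rvcbv(self) -> float:
        return self.dv_act / self.v0


@dataclass(frozen=True)
class CalibrationPoint:
    """One usable trial: q_h plus rest/active dR2* vs the normoxic baseline."""

    q_h: float
    dr2s_rest: float
    dr2s_act: float
    trial_id: Optional[int] = None
    condition: Optional[str] = None


@dataclass(frozen=True)
class CalibrationFit:
    """Result of the two-line calibration regression (abscissa 1 + q_h)."""

    m: float
    m_prime: float
    slope_rest: float
    slope_act: float
    intercept_rest: float
    intercept_act: float
    rvcbv: float
    q_act: float
    se_m: float = math.nan
    se_m_prime: float = math.nan
    se_rvcbv: float = math.nan
    se_q_act: float = math.nan
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "m": {"value": self.m, "units": "percent"},
            "m_prime": {"value": self.m_prime, "units": "percent"},
            "rvcbv": {"value": self.rvcbv, "units": "fraction"},
            "q_act": {"value": self.q_act, "units": "fraction"},
            "slope_rest": {"value": self.slope_rest, "units": "s^-1"},
            "slope_act": {"value": self.slope_act, "units": "s^-1"},
            "intercept_rest": {"value": self.intercept_rest, "units": "s^-1"},
            "intercept_act": {"value": self.intercept_act, "units": "s^-1"},
            "se": {
                "m": self.se_m,
                "m_prime": self.se_m_prime,
                "rvcbv": self.se_rvcbv,
                "q_act": self.se_q_act,
            },
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class CMRO2Result:
    rcbf: float
    q_act: float
    rcmro2: float

    def to_dict(self) -> dict:
        return {
            "rcbf": {"value": self.rcbf, "units": "fraction"},
            "q_act": {"value": self.q_act, "units": "fraction"},
            "rcmro2": {"value": self.rcmro2, "units": "fraction"},
        }


def percent_bold_to_dr2s(pct_bold, te: float):
    """dR2* (s^-1) from a % BOLD change: dR2* = -%BOLD / (100 * TE)."""
    if te <= 0:
        raise ValueError("te must be positive")
    out = -np.asarray(pct_bold, dtype=float) / (100.0 * te)
    return out if out.ndim else float(out)


def dr2s_to_percent_bold(dr2s, te: float):
    """Inverse of `percent_bold_to_dr2s`."""
    if te <= 0:
        raise ValueError("te must be positive")
    out = -np.asarray(dr2s, dtype=float) * 100.0 * te
    return out if out.ndim else float(out)


def forward_r2s(p: SignalModelParams, q_h: float, active: bool) -> float:
    """Model R2* at hyperoxia level q_h, resting or during the task."""
    if active:
        return p.k * (p.v0 + p.dv_act) * p.q0 * (1.0 + q_h + p.q_act) + p.r2_0
    return p.k * p.v0 * p.q0 * (1.0 + q_h) + p.r2_0


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Slope/intercept OLS with parameter covariance (nan when dof = 0)."""
    X = np.column_stack([np.ones_like(x), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = x.size - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else math.nan
    cov = sigma2 * xtx_inv
    return beta[1], beta[0], cov  # slope, intercept, cov([intercept, slope])


def fit_calibration(
    points: Iterable[CalibrationPoint], te: float
) -> CalibrationFit:
    """Fit the two-condition calibration from per-trial points.

    Unweighted OLS of dR2* against x = (1 + q_h), separately for the rest
    and active conditions; each usable trial contributes one point to each
    line. Requires at least two distinct q_h levels. Standard errors come
    from the OLS covariances with first-order propagation for the ratio
    (rvCBV) and intercept-gap quotient (q_act); they are nan at zero
    residual degrees of freedom.
    """
    pts = list(points)
    if te <= 0:
        raise ValueError("te must be positive")
    x = np.array([1.0 + p.q_h for p in pts], dtype=float)
    if x.size < 2 or np.unique(np.round(x, 12)).size < 2:
        raise ValueError(
            "rank deficient: need points at >= 2 distinct hyperoxia levels"
        )
    y_rest = np.array([p.dr2s_rest for p in pts], dtype=float)
    y_act = np.array([p.dr2s_act for p in pts], dtype=float)

    s_r, b_r, cov_r = _ols_line(x, y_rest)
    s_a, b_a, cov_a = _ols_line(x, y_act)
    if s_r <= 0:
        raise ValueError(
            f"non-physical fit: rest slope {s_r:.4g} s^-1 must be positive"
        )

    scale = 100.0 * te
    m = scale * s_r
    m_prime = scale * s_a
    rvcbv = s_a / s_r - 1.0
    q_act = (b_a - b_r) / s_a

    var_sr, var_sa = cov_r[1, 1], cov_a[1, 1]
    var_br, var_ba = cov_r[0, 0], cov_a[0, 0]
    cov_ba_sa = cov_a[0, 1]
    ratio = s_a / s_r
    se_rvcbv = abs(ratio) * math.sqrt(var_sa / s_a**2 + var_sr / s_r**2)
    # q_act = (b_a - b_r)/s_a: delta method with within-line covariance
    var_qact = (
        (var_ba + var_br) / s_a**2
        + q_act**2 * var_sa / s_a**2
        - 2.0 * q_act * cov_ba_sa / s_a**2
    )
    se_q_act = math.sqrt(var_qact) if var_qact == var_qact else math.nan

    return CalibrationFit(
        m=m,
        m_prime=m_prime,
        slope_rest=s_r,
        slope_act=s_a,
        intercept_rest=b_r,
        intercept_act=b_a,
        rvcbv=rvcbv,
        q_act=q_act,
        se_m=scale * math.sqrt(var_sr),
        se_m_prime=scale * math.sqrt(var_sa),
        se_rvcbv=se_rvcbv,
        se_q_act=se_q_act,
        n_points=x.size,
    )


def fick_rcmro2(q_act: float, rcbf: float) -> CMRO2Result:
    """Relative CMRO2 change from Fick's principle.

    Oxygen consumption is flow times arteriovenous content difference, so
    1 + rCMRO2 = (1 + q_act)(1 + rCBF).
    """
    if q_act <= -1.0 or rcbf <= -1.0:
        raise ValueError("q_act and rcbf must exceed -1")
    return CMRO2Result(
        rcbf=rcbf, q_act=q_act, rcmro2=(1.0 + q_act) * (1.0 + rcbf) - 1.0
    )


def delta_y_act(q_act: float, q0: float) -> float:
    """Absolute venous saturation increase on activation: -Q0 * q_act."""
    if not 0.0 < q0 < 1.0:
        raise ValueError("q0 must lie in (0, 1)")
    return -q0 * q_act


def rescale_q_act(q_act: float, q0_assumed: float, q0_measured: float) -> float:
    """Re-express q_act under a different baseline OEF (first order).

    q_h scales as 1/Q0, so to first order replacing an assumed Q0 with a
    measured one multiplies q_act by c = q0_assumed / q0_measured — the
    propagation used for reported per-subject values. The exact refit with
    rescaled q_h gives c*q_act + (c-1)*rvCBV/(1+rvCBV); this helper is its
    small-rvCBV limit. rvCBV itself is unaffected either way (both slopes
    rescale identically).
    """
    for q in (q0_assumed, q0_measured):
        if not 0.0 < q < 1.0:
            raise ValueError("Q0 values must lie in (0, 1)")
    return q_act * q0_assumed / q0_measured


def points_from_summaries(
    summaries: Sequence,
    qh_by_block: Sequence[float],
    te: float,
) -> list[CalibrationPoint]:
    """Build calibration points from trial summaries and per-block q_h."""
    pts = []
    for s in summaries:
        qh = float(qh_by_block[s.block_index])
        pts.append(
            CalibrationPoint(
                q_h=qh,
                dr2s_rest=percent_bold_to_dr2s(s.rest_pct, te),
                dr2s_act=percent_bold_to_dr2s(s.active_pct, te),
                trial_id=s.trial_index,
                condition=s.condition,
            )
        )
    return pts


def voxelwise_maps(
    volume: np.ndarray,
    mask: np.ndarray,
    paradigm,
    qh_by_block: Sequence[float],
    te: float,
    keep: Optional[Sequence[bool]] = None,
) -> dict[str, np.ndarray]:
    """Per-voxel calibration maps of M, M', rvCBV and q_act.

    `volume` has time on its last axis and any spatial shape; `mask` selects
    the voxels to fit. Each voxel runs the full conditioning pipeline
    (detrend, normalise, trial means) followed by `fit_calibration`. Voxels
    whose fit fails — zero variance, non-physical slope — are flagged NaN.
    """
    from .preprocess import detrend_linear, normalise_to_baseline, trial_summaries
    from .preprocess import RoiTimecourse, baseline_mask as _bmask

    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape[:-1]:
        raise ValueError("mask shape must match the volume's spatial shape")
    if not np.any(mask):
        raise ValueError("empty mask")
    times = paradigm.sample_times()
    if times.size != volume.shape[-1]:
        raise ValueError(
            f"volume has {volume.shape[-1]} timepoints but the paradigm grid "
            f"has {times.size}"
        )
    base = _bmask(paradigm, times)

    maps = {
        name: np.full(mask.shape, np.nan, dtype=np.float32)
        for name in ("m", "m_prime", "rvcbv", "q_act")
    }
    for idx in np.argwhere(mask):
        series = volume[tuple(idx)]
        if np.ptp(series) == 0:  # zero temporal variance: nothing to fit
            continue
        try:
            tc = RoiTimecourse(times, series, base)
            tc = normalise_to_baseline(detrend_linear(tc))
            summ = trial_summaries(tc, paradigm, keep=keep)
            fit = fit_calibration(points_from_summaries(summ, qh_by_block, te), te)
        except (ValueError, np.linalg.LinAlgError):
            continue
        maps["m"][tuple(idx)] = fit.m
        maps["m_prime"][tuple(idx)] = fit.m_prime
        maps["rvcbv"][tuple(idx)] = fit.rvcbv
        maps["q_act"][tuple(idx)] = fit.q_act
    return maps
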