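"""Oxygen physiology: from end-tidal O2 to venous deoxyhaemoglobin changes.

Hyperoxia raises arterial PO2; because arterial haemoglobin is nearly
saturated at normoxia, most of the extra oxygen travels dissolved in plasma.
With oxygen extraction assumed independent of the inspired level, the surplus
arterial content appears unextracted on the venous side and raises venous
saturation Yv. This module implements that chain: the Severinghaus
dissociation curve (310 K, pH 7.4), arterial oxygen content, the venous
balance, and the per-block relative deoxyhaemoglobin change q_h that drives
the calibration regressions.

End-tidal PO2 is used as the arterial PaO2 directly: with sequential gas
delivery the end-tidal-to-arterial gradient is negligible for this purpose.
This is a model assumption, not a configuration knob.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import Paradigm

__all__ = [
    "GasConstants",
    "EndTidalTrace",
    "OxygenationState",
    "HyperoxiaContrast",
    "sa_o2",
    "ca_o2",
    "venous_state",
    "hyperoxia_contrast",
    "petco2_trial_qc",
]


@dataclass(frozen=True)
class GasConstants:
    """Physiological and physical constants of the blood-gas model.

    Susceptibilities are volume susceptibilities relative to water in cgs
    units of 1e-6; molar susceptibilities in 1e-6 cm^3/mol.

    Attributes
    ----------
    phi : float
        Oxygen-carrying capacity of haemoglobin, ml(O2)/g.
    hb : float
        Haemoglobin concentration, g/dl blood.
    epsilon : float
        O2 plasma solubility, ml O2/(dl blood * mm Hg).
    dchi_oxy, dchi_deoxy : float
        Volume susceptibility of fully oxy-/deoxygenated haemoglobin
        relative to water, x1e-6 cgs.
    chi_m_o2, chi_m_n2 : float
        Molar susceptibility of O2 / N2 gas, x1e-6 cm^3/mol.
    v_m : float
        Molar gas volume, L/mol (room temperature, 1 atm).
    hct : float
        Haematocrit fraction.
    """

    phi: float = 1.34
    hb: float = 15.0
    epsilon: float = 0.0031
    dchi_oxy: float = -0.017
    dchi_deoxy: float = 0.247
    chi_m_o2: float = 3415.0
    chi_m_n2: float = -12.0
    v_m: float = 24.5
    hct: float = 0.4

    def __post_init__(self) -> None:
        for name in ("phi", "hb", "epsilon", "dchi_deoxy", "chi_m_o2", "v_m", "hct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"GasConstants.{name} must be positive")
        if self.dchi_oxy >= 0:
            raise ValueError("dchi_oxy must be negative (oxyHb is diamagnetic)")
        if self.chi_m_n2 >= 0:
            raise ValueError("chi_m_n2 must be negative")

    @property
    def dchi_do(self) -> float:
        """Deoxy-minus-oxy haemoglobin susceptibility difference (x1e-6)."""
        return self.dchi_deoxy - self.dchi_oxy


DEFAULT_CONSTANTS = GasConstants()


@dataclass
class EndTidalTrace:
    """Sampled end-tidal gas trace.

    times in seconds from paradigm start (strictly increasing), partial
    pressures in mm Hg.
    """

    times: np.ndarray
    peto2: np.ndarray
    petco2: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.peto2 = np.asarray(self.peto2, dtype=float)
        self.petco2 = np.asarray(self.petco2, dtype=float)
        if not (self.times.shape == self.peto2.shape == self.petco2.shape):
            raise ValueError("times, peto2, petco2 must have equal length")
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("trace must be a 1-D series with >= 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.peto2 <= 0) or np.any(self.petco2 <= 0):
            raise ValueError("partial pressures must be positive")


@dataclass(frozen=True)
class OxygenationState:
    """Arterial/venous oxygenation derived from a single PaO2.

    pao2 in mm Hg; sao2 arterial saturation fraction; cao2 arterial O2
    content in ml/dl blood; yv venous saturation fraction; q venous
    deoxyhaemoglobin fraction (1 - yv).
    """

    pao2: float
    sao2: float
    cao2: float
    yv: float
    q: float


@dataclass(frozen=True)
class HyperoxiaContrast:
    """Per-block hyperoxia deoxyhaemoglobin change.

    q0 is the baseline dHb fraction (numerically the OEF), dq_h the absolute
    change in venous dHb fraction relative to the normoxic baseline, and
    q_h = dq_h / q0 the relative change entering the calibration abscissa.
    """

    block_index: int
    label: str
    pao2: float
    q0: float
    dq_h: float
    q_h: float


def sa_o2(pao2):
    """Arterial haemoglobin O2 saturation from PaO2 (Severinghaus form).

    SaO2 = (23400 / (PaO2^3 + 150 PaO2) + 1)^-1, valid at 310 K, pH 7.4.
    Strictly increasing in PaO2 and bounded in (0, 1).

    Parameters
    ----------
    pao2 : float or array_like
        Arterial O2 partial pressure, mm Hg (> 0).
    """
    p = np.asarray(pao2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pao2 must be positive (mm Hg)")
    out = 1.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)
    return out if out.ndim else float(out)


def ca_o2(pao2, c: GasConstants = DEFAULT_CONSTANTS):
    """Total arterial O2 content, ml(O2)/dl blood: Hb-bound plus dissolved.

    CaO2 = phi * [Hb] * SaO2(PaO2) + epsilon * PaO2.
    """
    p = np.asarray(pao2, dtype=float)
    out = c.phi * c.hb * sa_o2(p) + c.epsilon * p
    return out if out.ndim else float(out)


def venous_state(
    pao2: float,
    oef: float,
    baseline_pao2: float = 110.0,
    c: GasConstants = DEFAULT_CONSTANTS,
) -> OxygenationState:
    """Venous oxygenation for a given PaO2 under level-independent extraction.

    Oxygen extraction OE = CaO2(baseline) * OEF is fixed at its normoxic
    value; the venous content is what remains, and (venous haemoglobin being
    far from saturated) is carried almost entirely on haemoglobin:

        Yv = (CaO2(PaO2) - OE) / (phi * [Hb]),   Q = 1 - Yv.

    Raises an error when the implied Yv leaves (0, 1) — infeasible
    physiology for the requested inputs.
    """
    if not 0.0 < oef < 1.0:
        raise ValueError("oef must lie in (0, 1)")
    oe = ca_o2(baseline_pao2, c) * oef
    yv = (ca_o2(pao2, c) - oe) / (c.phi * c.hb)
    if not 0.0 < yv < 1.0:
        raise ValueError(
            f"infeasible physiology: venous saturation {yv:.3f} outside (0, 1) "
            f"for pao2={pao2}, oef={oef}, baseline={baseline_pao2}"
        )
    return OxygenationState(
        pao2=float(pao2),
        sao2=sa_o2(pao2),
        cao2=ca_o2(pao2, c),
        yv=float(yv),
        q=float(1.0 - yv),
    )


def pao2_for_dyv(
    dyv: float,
    baseline_pao2: float = 110.0,
    c: GasConstants = DEFAULT_CONSTANTS,
) -> float:
    """PaO2 (mm Hg) producing a given venous saturation increase over baseline.

    Inverts the venous balance: solves CaO2(PaO2) - CaO2(baseline) =
    phi * [Hb] * dyv. Independent of the assumed OEF (extraction cancels).
    """
    if dyv <= 0:
        raise ValueError("dyv must be positive (hyperoxia raises Yv)")
    from scipy.optimize import brentq

    target = ca_o2(baseline_pao2, c) + c.phi * c.hb * dyv
    hi = 5000.0
    if ca_o2(hi, c) < target:
        raise ValueError(f"dyv = {dyv} unreachable below {hi} mm Hg")
    return float(brentq(lambda p: ca_o2(p, c) - target, baseline_pao2, hi))


def _block_window_mean(
    times: np.ndarray, values: np.ndarray, start: float, end: float, window_s: float
) -> float:
    """Mean of `values` over the steady-state tail [max(start, end-window), end)."""
    lo = max(start, end - window_s)
    sel = (times >= lo) & (times < end)
    if not np.any(sel):
        raise ValueError(f"no trace samples in steady-state window [{lo}, {end})")
    return float(values[sel].mean())


def hyperoxia_contrast(
    trace: EndTidalTrace,
    paradigm: "Paradigm",
    q0: float,
    c: GasConstants = DEFAULT_CONSTANTS,
    window_s: float = 120.0,
) -> list[HyperoxiaContrast]:
    """Per-gas-block relative venous dHb change q_h from a measured O2 trace.

    The arterial PaO2 of each block is the mean end-tidal PO2 over the
    block's steady-state tail (the final `window_s` seconds, default 2 min).
    The normoxic reference PaO2 pools the steady-state windows of every
    normoxia block; normoxia blocks are assigned q_h = 0 by construction.

    dq_h is independent of the assumed q0 (extraction cancels in the
    difference); q_h = dq_h / q0 inherits a 1/q0 scaling.
    """
    if not 0.0 < q0 < 1.0:
        raise ValueError("q0 must lie in (0, 1)")
    norm_vals = []
    for b in paradigm.blocks:
        if b.label == "normoxia":
            lo = max(b.start, b.end - window_s)
            sel = (trace.times >= lo) & (trace.times < b.end)
            norm_vals.append(trace.peto2[sel])
    norm_vals = np.concatenate(norm_vals) if norm_vals else np.array([])
    if norm_vals.size == 0:
        raise ValueError("paradigm has no normoxia samples to define baseline PaO2")
    baseline_pao2 = float(norm_vals.mean())
    q_base = venous_state(baseline_pao2, q0, baseline_pao2, c).q

    out = []
    for i, b in enumerate(paradigm.blocks):
        if b.label == "normoxia":
            out.append(HyperoxiaContrast(i, b.label, baseline_pao2, q0, 0.0, 0.0))
            continue
        pao2 = _block_window_mean(trace.times, trace.peto2, b.start, b.end, window_s)
        dq = venous_state(pao2, q0, baseline_pao2, c).q - q_base
        out.append(HyperoxiaContrast(i, b.label, pao2, q0, float(dq), float(dq / q0)))
    return out


def petco2_trial_qc(
    trace: EndTidalTrace,
    paradigm: "Paradigm",
    threshold: float = 1.0,
) -> np.ndarray:
    """Keep/discard flag per motor trial based on end-tidal CO2 stability.

    The normocapnia reference is the mean PETCO2 over all baseline
    timepoints (normoxia, outside trials and their 30-s aftermath). A trial
    is discarded when any CO2 sample inside its trial cycle (tapping window
    plus the following rest window) deviates from that reference by more
    than `threshold` mm Hg — such transients, typically overshoots during a
    gas transition, would contaminate the trial's BOLD averages.

    Returns a boolean array, True = keep.
    """
    from .preprocess import baseline_mask  # local import avoids cycle

    base = baseline_mask(paradigm, trace.times)
    if not np.any(base):
        raise ValueError("no baseline timepoints to define normocapnia reference")
    ref = float(trace.petco2[base].mean())

    keep = np.ones(len(paradigm.trials), dtype=bool)
    for i, tr in enumerate(paradigm.trials):
        sel = (trace.times >= tr.onset) & (trace.times < tr.off_end)
        if not np.any(sel):
            warnings.warn(
                f"trial {i}: no CO2 samples in [{tr.onset}, {tr.off_end}); discarded",
                stacklevel=2,
            )
            keep[i] = False
            continue
        if np.any(np.abs(trace.petco2[sel] - ref) > threshold):
            keep[i] = False
    return keep
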