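"""Volume-susceptibility bookkeeping for blood and breathing gas.

All values are volume susceptibilities relative to water/tissue in cgs units
of 1e-6, matching the convention of the blood-oximetry literature. Each
operation is linear in its driving variable.

Unit bridge for dissolved oxygen: epsilon is quoted per decilitre of blood
(ml O2 / (dl * mm Hg)), so epsilon * PaO2 / 100 is the dimensionless volume
fraction of (gas-phase-equivalent) O2 in blood; chi_m / (V_m * 1000)
converts the molar susceptibility (cm^3/mol) at molar volume V_m (L/mol)
into the volume susceptibility of the pure gas.
"""

from __future__ import annotations

import numpy as np

from .gas import DEFAULT_CONSTANTS, GasConstants

__all__ = [
    "dissolved_o2_chi",
    "hb_chi_change",
    "air_chi_change",
    "blood_chi",
    "gas_volume_chi",
    "cgs_to_si",
]


def gas_volume_chi(chi_m: float, c: GasConstants = DEFAULT_CONSTANTS) -> float:
    """Volume susceptibility (x1e-6 cgs) of a pure gas from its molar value."""
    return chi_m / (c.v_m * 1e3)


def dissolved_o2_chi(pao2, c: GasConstants = DEFAULT_CONSTANTS):
    """Susceptibility contribution of O2 dissolved in blood plasma (x1e-6).

    chi_v = chi_m(O2)/(V_m * 10^3) * epsilon * PaO2 / 100 — the pure-gas
    volume susceptibility weighted by the dissolved-O2 volume fraction.
    Linear in PaO2; ~0.0005e-6 at normoxia, ~0.0022e-6 at 500 mm Hg.
    """
    p = np.asarray(pao2, dtype=float)
    if np.any(p < 0):
        raise ValueError("pao2 must be non-negative")
    out = gas_volume_chi(c.chi_m_o2, c) * (c.epsilon * p / 100.0)
    return out if out.ndim else float(out)


def hb_chi_change(delta_y, c: GasConstants = DEFAULT_CONSTANTS):
    """Blood susceptibility change (x1e-6) for a saturation change delta_y.

    A saturation increase makes blood less paramagnetic:
    dchi_v = -delta_y * (dchi_deoxy - dchi_oxy) * Hct.
    """
    dy = np.asarray(delta_y, dtype=float)
    if np.any(np.abs(dy) > 1.0):
        raise ValueError("|delta_y| cannot exceed 1")
    out = -dy * c.dchi_do * c.hct
    return out if out.ndim else float(out)


def air_chi_change(
    fo2_from: float, fo2_to: float, c: GasConstants = DEFAULT_CONSTANTS
) -> float:
    """Change in air volume susceptibility (x1e-6) for an O2 fraction change.

    The balance of the mixture is N2; the change is
    (fo2_to - fo2_from) * (chi_m(O2) - chi_m(N2)) / (V_m * 10^3).
    """
    for f in (fo2_from, fo2_to):
        if not 0.0 <= f <= 1.0:
            raise ValueError("O2 fractions must lie in [0, 1]")
    return (fo2_to - fo2_from) * gas_volume_chi(c.chi_m_o2 - c.chi_m_n2, c)


def blood_chi(y, c: GasConstants = DEFAULT_CONSTANTS):
    """Blood volume susceptibility relative to water (x1e-6) at saturation y.

    Treats plasma and tissue as water: chi = Hct * [y*dchi_oxy +
    (1-y)*dchi_deoxy]. Strictly decreasing in y; the basis of the
    phase-ratio oxygenation estimate.
    """
    yy = np.asarray(y, dtype=float)
    if np.any((yy < 0) | (yy > 1)):
        raise ValueError("saturation must lie in [0, 1]")
    out = c.hct * (yy * c.dchi_oxy + (1.0 - yy) * c.dchi_deoxy)
    return out if out.ndim else float(out)


def cgs_to_si(chi_cgs_1e6: float) -> float:
    """Convert a x1e-6 cgs volume susceptibility to dimensionless SI (chi_SI = 4*pi*chi_cgs)."""
    return 4.0 * np.pi * chi_cgs_1e6 * 1e-6
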