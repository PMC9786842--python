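"""Fractionation constants and fitted respiration parameters.

All isotope quantities are carried in permil (‰) vs V-PDB throughout the
package; conductances are per all-sided needle area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.3145

#: 13C/12C ratio of the V-PDB standard, used to split bulk CO2 into
#: isotopologue mole fractions and to convert flux ratios to delta values.
R_VPDB = 0.0111802

#: Celsius -> Kelvin offset.
T0_KELVIN = 273.15


@dataclass(frozen=True)
class DiscriminationParams:
    """Fractionation factors of the steady-state discrimination model.

    Attributes
    ----------
    a : float
        Fractionation by gaseous diffusion through stomata, ‰.
    b : float
        Fractionation by carboxylation (Rubisco), ‰.
    a_m : float
        Fractionation during mesophyll CO2 transfer, ‰.
    f : float
        Photorespiratory fractionation, ‰ (8 by default; 11 is the
        common alternative used for sensitivity analysis).
    e : float
        Day-respiratory fractionation, ‰ (negative: respired CO2 is
        13C-enriched relative to its substrate).
    b_prime : float
        Net carboxylation fractionation of the simple two-term model, ‰.
    g_m : float
        Mesophyll conductance, mol m-2 s-1 per all-sided needle area.
        ``math.inf`` switches the mesophyll drawdown term off.
    """

    a: float = 4.4
    b: float = 29.0
    a_m: float = 1.8
    f: float = 8.0
    e: float = -6.0
    b_prime: float = 27.0
    g_m: float = 0.127

    def __post_init__(self) -> None:
        if not (self.b > self.a > 0):
            raise ValueError("require b > a > 0")
        if not (self.g_m > 0):
            raise ValueError("g_m must be positive (use math.inf to disable)")

    @property
    def infinite_gm(self) -> bool:
        return math.isinf(self.g_m)


@dataclass(frozen=True)
class RespirationParams:
    """Mitochondrial respiration temperature response R_d(T).

    ``R_d = R_d0 * exp(H_alpha * (Tl - 25) / (298 * R * (Tl + 273.15)))``
    with R_d0 the rate at 25 °C (µmol m-2 s-1) and H_alpha an activation
    energy (J mol-1). ``light_inhibited`` forces R_d = 0 inside the
    discrimination model (daytime light inhibition), while the night-time
    efflux keeps the full response.
    """

    r_d0: float = 0.8
    h_alpha: float = 40_000.0
    light_inhibited: bool = False

    def __post_init__(self) -> None:
        if self.r_d0 < 0:
            raise ValueError("r_d0 must be non-negative")


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and plumbing of one shoot chamber.

    The chamber is non-airtight: sample air drawn to the analysers at
    ``sample_flow`` is replaced by ambient air leaking in, which gives the
    first-order dilution mass balance used for flux fitting.
    """

    volume_dm3: float = 1.0
    needle_area_m2: float = 0.01
    sample_flow_dm3_min: float = 1.0
    closure_seconds: float = 65.0
    fast_dt_s: float = 0.5
    slow_dt_s: float = 5.0

    def __post_init__(self) -> None:
        if self.volume_dm3 <= 0 or self.needle_area_m2 <= 0 or self.sample_flow_dm3_min <= 0:
            raise ValueError("chamber volume, area and flow must be positive")


def delta_to_ratio(delta_permil: float) -> float:
    """Convert δ13C (‰ vs V-PDB) to an absolute 13C/12C ratio."""
    return R_VPDB * (1.0 + delta_permil / 1000.0)


def ratio_to_delta(ratio) -> float:
    """Convert an absolute 13C/12C ratio to δ13C (‰ vs V-PDB)."""
    return (ratio / R_VPDB - 1.0) * 1000.0
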