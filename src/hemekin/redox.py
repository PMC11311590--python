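"""Nernst-equation design of ferro/ferricyanide redox buffers.

A mixture of potassium ferrocyanide (reduced) and ferricyanide (oxidized)
poises the solution potential through the one-electron Nernst relation

    Em = E°' + (RT/F) · ln([ox]/[red])

so the mixing ratio is a dial for the ambient redox potential.  With the
couple's midpoint at +420 mV, a 6:1 ferro:ferri ratio poises the buffer at
~374 mV (≈370 mV to the nearest 10), low enough for ferrocyanide to act as
a one-electron peroxidase substrate for cytochrome c without radical
intermediates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import constants

__all__ = ["RedoxCouple", "nernst_em", "ratio_for_em", "thermal_voltage_mV"]


def thermal_voltage_mV(temperature_K: float = 298.15) -> float:
    """RT/F in millivolts (25.693 mV at 25 °C)."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return constants.R * temperature_K / constants.value("Faraday constant") * 1e3


@dataclass(frozen=True)
class RedoxCouple:
    """A one-electron redox couple at given oxidized/reduced concentrations.

    Parameters
    ----------
    midpoint_mV : float
        Standard (1:1) midpoint potential E°' in mV.
    conc_ox, conc_red : float
        Oxidized (ferricyanide) and reduced (ferrocyanide) concentrations,
        mol/L.  Only their ratio matters for the potential.
    temperature_K : float
        Temperature in kelvin, default 298.15 (assays run at 25 °C).
    """

    midpoint_mV: float
    conc_ox: float
    conc_red: float
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.conc_ox <= 0 or self.conc_red <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def ratio_red_ox(self) -> float:
        """Reduced:oxidized concentration ratio (6.0 for a 6:1 buffer)."""
        return self.conc_red / self.conc_ox


def nernst_em(couple: RedoxCouple) -> float:
    """Solution potential of the couple in mV.

    One-electron Nernst relation with natural logarithm:
    ``Em = E°' + (RT/F)·ln([ox]/[red])``.
    """
    vt = thermal_voltage_mV(couple.temperature_K)
    return couple.midpoint_mV + vt * math.log(couple.conc_ox / couple.conc_red)


def ratio_for_em(
    midpoint_mV: float, target_mV: float, temperature_K: float = 298.15
) -> float:
    """Reduced:oxidized ratio that poises the buffer at ``target_mV``.

    Closed-form inverse of :func:`nernst_em`:
    ``r = exp((E°' − Em) · F/(RT))``.  Returns e.g. ~6.0 for a +420 mV
    couple targeted at 374 mV.
    """
    if not math.isfinite(target_mV):
        raise ValueError("target potential must be finite")
    vt = thermal_voltage_mV(temperature_K)
    return math.exp((midpoint_mV - target_mV) / vt)
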