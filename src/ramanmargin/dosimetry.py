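"""Laser-exposure arithmetic for probe safety assessment.

Average irradiance over the hazard-evaluation limiting aperture, and the
ANSI Z136.1 maximum permissible exposure (MPE) for skin under long
continuous-wave exposure in the 700-1050 nm band, where the wavelength
correction factor is C_A = 10^(2 (lambda - 700) / 1000).
"""
from __future__ import annotations

import math

__all__ = ["irradiance", "mpe_skin_cw", "dosimetry_table"]


def irradiance(power_mw: float, aperture_diameter_mm: float) -> float:
    """Average irradiance in W/cm^2 of a beam over a circular limiting aperture.

    ``power / (pi (d/2)^2)`` with unit conversion; e.g. 100 mW over the
    3.5-mm hazard-evaluation aperture gives 1.04 W/cm^2.
    """
    if power_mw <= 0 or aperture_diameter_mm <= 0:
        raise ValueError("power and aperture diameter must be positive")
    power_w = power_mw / 1000.0
    radius_cm = aperture_diameter_mm / 20.0
    return power_w / (math.pi * radius_cm**2)


def mpe_skin_cw(wavelength_nm: float, duration_s: float) -> float:
    """ANSI skin MPE in W/cm^2 for continuous exposure longer than 10 s.

    MPE = 0.2 * C_A with C_A = 10^(2 (lambda - 700)/1000); 0.2 W/cm^2 at
    700 nm, ~0.3 W/cm^2 at 785 nm. Only the t > 10 s branch is
    implemented; short exposures follow a different rule and are rejected.
    """
    if not 700.0 <= wavelength_nm <= 1050.0:
        raise ValueError("wavelength must lie in [700, 1050] nm for this MPE formula")
    if duration_s <= 10.0:
        raise ValueError("only the continuous-exposure branch (duration > 10 s) is implemented")
    c_a = 10.0 ** (2.0 * (wavelength_nm - 700.0) / 1000.0)
    return 0.2 * c_a


def dosimetry_table(
    power_mw: float = 100.0,
    spot_diameter_mm: float = 0.5,
    limiting_aperture_mm: float = 3.5,
    wavelength_nm: float = 785.0,
    duration_s: float = 40.0,
) -> dict[str, float]:
    """Summary of delivered irradiance against the applicable skin MPE."""
    return {
        "power_mw": power_mw,
        "wavelength_nm": wavelength_nm,
        "duration_s": duration_s,
        "irradiance_spot_w_cm2": irradiance(power_mw, spot_diameter_mm),
        "irradiance_limiting_aperture_w_cm2": irradiance(power_mw, limiting_aperture_mm),
        "mpe_skin_w_cm2": mpe_skin_cw(wavelength_nm, duration_s),
    }
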