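"""Unit conventions and physical constants.

Internal unit system: rates in µs⁻¹, time in µs, concentrations in mM.
All I/O at the package boundary is SI (seconds, W/cm², M) with explicit
unit suffixes in column names; conversion happens here.
"""

H_PLANCK_J_S = 6.62607015e-34
C_LIGHT_M_S = 2.99792458e8

#: Dissolved O2 concentration (mM) of air-saturated aqueous buffer at room
#: temperature; used to convert air-saturation fractions to molar units.
O2_AIR_SAT_MM = 0.27


def per_M_s_to_per_mM_us(k: float) -> float:
    """Convert a bimolecular quench coefficient from M⁻¹s⁻¹ to mM⁻¹µs⁻¹."""
    return k * 1e-9


def per_mM_us_to_per_M_s(k: float) -> float:
    return k * 1e9


def photon_flux(irradiance_W_cm2: float, wavelength_nm: float) -> float:
    """Photon flux Φ (photons cm⁻² s⁻¹) from irradiance.

    Φ = I·λ/(h·c): each photon at wavelength λ carries energy h·c/λ.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    if irradiance_W_cm2 < 0:
        raise ValueError("irradiance must be non-negative")
    energy = H_PLANCK_J_S * C_LIGHT_M_S / (wavelength_nm * 1e-9)
    return irradiance_W_cm2 / energy
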