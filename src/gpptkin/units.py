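"""Unit conversions between gas mixing ratios and molar concentrations."""

R_GAS = 8.314462618  # J mol-1 K-1
P_ATM = 101325.0  # Pa


def mixing_ratio_to_umol_per_l(ppmv, temperature=298.15, pressure=P_ATM):
    """Convert a trace-gas mixing ratio to a molar concentration in air.

    Assumes ideal-gas behaviour: 1 µl l⁻¹ corresponds to
    P/(R·T)·10⁻³ µmol (l air)⁻¹, i.e. ≈0.0409 µmol l⁻¹ at 298.15 K
    and 1 atm (so 900 µl l⁻¹ CH4 ≈ 36.8 µmol l⁻¹, commonly rounded
    to ~40 µM).

    Parameters
    ----------
    ppmv : float or ndarray
        Mixing ratio in µl (l air)⁻¹ (= ppmv).
    temperature : float
        Air temperature in K.
    pressure : float
        Air pressure in Pa.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return ppmv * pressure / (R_GAS * temperature) * 1e-3


def umol_per_l_to_mixing_ratio(umol_l, temperature=298.15, pressure=P_ATM):
    """Inverse of :func:`mixing_ratio_to_umol_per_l`."""
    return umol_l / (pressure / (R_GAS * temperature) * 1e-3)
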