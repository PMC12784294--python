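"""Unit conversions used across the pipeline."""

from __future__ import annotations


def excitation_wavenumber_cm1(wavelength_nm: float) -> float:
    """Vacuum wavenumber (cm^-1) of an excitation wavelength in nm.

    514 nm -> 19455.3 cm^-1 (to the printed precision).
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 1e7 / wavelength_nm


def celsius_to_kelvin(theta_c: float) -> float:
    """25 degC -> 298.15 K."""
    kelvin = theta_c + 273.15
    if kelvin < 0:
        raise ValueError("temperature below absolute zero")
    return kelvin


def wavelength_interval_to_wavenumber(delta_lambda_nm: float, wavelength_nm: float) -> float:
    """Convert a spectral resolution Delta-lambda at wavelength lambda to a
    wavenumber interval via d(nu~) = d(lambda) / lambda^2.

    0.135 nm at the 576.964 nm spectral center -> about 4 cm^-1, inside
    the 3-5 cm^-1 bracket quoted for a 600 g/mm spectrograph.
    """
    if wavelength_nm <= 0 or delta_lambda_nm < 0:
        raise ValueError("wavelength must be positive and interval non-negative")
    return delta_lambda_nm * 1e7 / wavelength_nm**2
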