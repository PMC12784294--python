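"""Conversion of DFT Raman activities to a broadened intensity spectrum.

Quantum-chemistry codes report a Raman *activity* S_j (A^4 amu^-1) per
normal mode; an observable Stokes intensity follows from the standard
scattering conversion

    I_j  proportional to  (nu0 - nu_j)^4 * S_j
                          / ( nu_j * [1 - exp(-h c nu_j / (k_B T))] )

with nu0 the excitation wavenumber, nu_j the (scaled) mode wavenumber
and the bracket the thermal (Boltzmann) occupation factor. Calculated
harmonic frequencies are first multiplied by an empirical scale factor
(default 0.9626 for B3LYP/def2-TZVPP-class calculations); the converted
stick spectrum is broadened with unit-peak-height Lorentzians (FWHM
15 cm^-1 by default) and max-normalized to 1 for comparison with
measured, display-normalized spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import constants

from .containers import Spectrum
from .phantom import lorentzian

#: 514 nm excitation in vacuum wavenumbers.
DEFAULT_EXCITATION_CM1 = 1e7 / 514.0  # 19455.3 cm^-1


@dataclass(frozen=True)
class RamanModeTable:
    """DFT vibrational modes: frequency (cm^-1), activity (A^4 amu^-1),
    and — once converted — normalized intensity."""

    frequencies: np.ndarray
    activities: np.ndarray
    intensities: Optional[np.ndarray] = None

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.activities, dtype=float)
        if f.shape != a.shape or f.ndim != 1:
            raise ValueError("frequencies and activities must be matching 1-D arrays")
        if np.any(f <= 0):
            raise ValueError("mode frequencies must be positive")
        if np.any(a < 0):
            raise ValueError("Raman activities must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "activities", a)

    @property
    def n_modes(self) -> int:
        return self.frequencies.size


class ConversionSpec(BaseModel):
    """Parameters of the activity-to-intensity conversion."""

    excitation_cm1: float = Field(default=DEFAULT_EXCITATION_CM1, gt=0)
    temperature_k: float = Field(default=298.15, gt=0)
    frequency_scale: float = Field(default=0.9626, gt=0, le=1.2)
    fwhm_cm1: float = Field(default=15.0, gt=0)
    #: ``difference`` uses (nu0 - nu_j)^4 (Stokes-shifted scattered
    #: frequency); ``excitation`` is the alternative nu0^4 convention.
    fourth_power: Literal["difference", "excitation"] = "difference"
    #: Lorentzians of unit peak height by default; ``area`` normalizes
    #: each profile to unit area instead.
    lineshape_norm: Literal["height", "area"] = "height"

    @model_validator(mode="after")
    def _positive_bracket(self):
        return self


def scale_frequencies(table: RamanModeTable, factor: float) -> RamanModeTable:
    """Multiply all mode frequencies by the empirical scale factor."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return replace(table, frequencies=table.frequencies * factor)


def thermal_occupation_bracket(nu_cm1, temperature_k: float) -> np.ndarray:
    """1 - exp(-h c nu / (k_B T)) for wavenumbers in cm^-1."""
    nu = np.asarray(nu_cm1, dtype=float)
    hc_over_kb = constants.h * constants.c / constants.k  # m K
    return 1.0 - np.exp(-hc_over_kb * 100.0 * nu / temperature_k)


def activity_to_intensity(
    table: RamanModeTable, spec: ConversionSpec | None = None
) -> RamanModeTable:
    """Convert activities to intensities, normalized so max I_j = 1.

    Apply *after* frequency scaling. Modes at or above the excitation
    wavenumber are rejected.
    """
    spec = spec or ConversionSpec()
    nu = table.frequencies
    if np.any(nu >= spec.excitation_cm1):
        bad = float(nu[nu >= spec.excitation_cm1][0])
        raise ValueError(
            f"mode at {bad:g} cm^-1 is not below the excitation wavenumber "
            f"{spec.excitation_cm1:g} cm^-1"
        )
    if spec.fourth_power == "difference":
        prefactor = (spec.excitation_cm1 - nu) ** 4
    else:
        prefactor = np.full_like(nu, spec.excitation_cm1**4)
    intensity = prefactor * table.activities / (
        nu * thermal_occupation_bracket(nu, spec.temperature_k)
    )
    top = intensity.max()
    if top > 0:
        intensity = intensity / top
    return replace(table, intensities=intensity)


def broaden(
    table: RamanModeTable, axis: np.ndarray, spec: ConversionSpec | None = None
) -> Spectrum:
    """Lorentzian-broaden the converted stick spectrum onto an axis.

    The result is max-normalized to 1 over the axis, matching the
    display convention of measured spectra. Doubling every activity
    leaves it unchanged.
    """
    spec = spec or ConversionSpec()
    if table.intensities is None:
        table = activity_to_intensity(table, spec)
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    for nu, height in zip(table.frequencies, table.intensities):
        profile = lorentzian(axis, nu, spec.fwhm_cm1)
        if spec.lineshape_norm == "area":
            profile = profile * 2.0 / (np.pi * spec.fwhm_cm1)
        out += height * profile
    top = out.max()
    if top > 0:
        out = out / top
    return Spectrum(axis, out)


def dft_reference_spectrum(
    table: RamanModeTable, axis: np.ndarray, spec: ConversionSpec | None = None
) -> Spectrum:
    """Full pipeline: scale frequencies, convert activities, broaden."""
    spec = spec or ConversionSpec()
    scaled = scale_frequencies(table, spec.frequency_scale)
    converted = activity_to_intensity(scaled, spec)
    return broaden(converted, axis, spec)
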