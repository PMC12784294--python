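"""Corrections for stimulated Raman scattering (SRS) image stacks.

Stimulated Raman loss is bilinear in the pump and Stokes beam powers, so
per-frame power fluctuations are compensated by scaling each frame with
(P_pump_ref * P_Stokes_ref) / (P_pump * P_Stokes) relative to the first
frame (a pump-only model is selectable). Non-Raman background is removed
by subtracting an off-resonance frame (2500 cm^-1), spectra are
normalized to a 0-1 range within the 2050-2300 cm^-1 silent window, and
z-stacks collapse by maximum (or mean) projection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np

from .containers import Spectrum


@dataclass(frozen=True)
class SRSFrame:
    """One SRS image frame plus its acquisition metadata."""

    image: np.ndarray  # (rows, cols)
    wavenumber: float  # pump-Stokes detuning in cm^-1
    pump_power: float
    stokes_power: float
    z_index: Optional[int] = None

    def __post_init__(self):
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("SRS frame image must be 2-D")
        if self.pump_power <= 0 or self.stokes_power <= 0:
            raise ValueError("beam powers must be positive")
        object.__setattr__(self, "image", img)


def _check_shapes(frames: list[SRSFrame]) -> None:
    if not frames:
        raise ValueError("empty SRS stack")
    shape = frames[0].image.shape
    for i, frame in enumerate(frames):
        if frame.image.shape != shape:
            raise ValueError(f"frame {i} shape {frame.image.shape} != {shape}")


def power_correct(
    frames: list[SRSFrame], model: Literal["bilinear", "pump"] = "bilinear"
) -> tuple[list[SRSFrame], np.ndarray]:
    """Rescale every frame to the first frame's beam powers.

    Returns the corrected frames and the applied correction factors.
    Note the correction is not idempotent: once applied, all powers are
    effectively equal, but applying it to already-corrected data with
    the original metadata would rescale again.
    """
    _check_shapes(frames)
    ref = frames[0]
    factors = []
    corrected = []
    for frame in frames:
        if model == "bilinear":
            factor = (ref.pump_power * ref.stokes_power) / (
                frame.pump_power * frame.stokes_power
            )
        else:
            factor = ref.pump_power / frame.pump_power
        factors.append(factor)
        corrected.append(replace(frame, image=frame.image * factor))
    return corrected, np.array(factors)


def off_resonance_subtract(frame: np.ndarray, off_frame: np.ndarray) -> np.ndarray:
    """Pixelwise subtraction of the off-resonance image; negatives preserved."""
    frame = np.asarray(frame, dtype=float)
    off = np.asarray(off_frame, dtype=float)
    if frame.shape != off.shape:
        raise ValueError(f"shape mismatch: {frame.shape} vs {off.shape}")
    return frame - off


SILENT_WINDOW = (2050.0, 2300.0)


def normalize_silent(spectrum: Spectrum) -> Spectrum:
    """Affine map sending the 2050-2300 cm^-1 window to the 0-1 range.

    The same affine map is applied to the whole spectrum, so values
    outside the window may leave [0, 1]. Idempotent.
    """
    lo, hi = SILENT_WINDOW
    sel = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if sel.sum() < 2:
        raise ValueError(
            f"axis must cover {lo:g}-{hi:g} cm^-1 with at least 2 samples"
        )
    window = spectrum.intensities[sel]
    mn, mx = float(window.min()), float(window.max())
    if mx == mn:
        raise ValueError("spectrum is constant within the silent window (zero range)")
    return Spectrum(spectrum.wavenumbers, (spectrum.intensities - mn) / (mx - mn))


def z_project(
    frames: list[SRSFrame], mode: Literal["max", "mean"] = "max"
) -> np.ndarray:
    """Collapse a z-stack to a single image (pixelwise max or mean)."""
    _check_shapes(frames)
    stack = np.stack([f.image for f in frames], axis=0)
    return stack.max(axis=0) if mode == "max" else stack.mean(axis=0)
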