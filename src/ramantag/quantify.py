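"""Band-area quantitation and the nuclear-DNA-normalized abundance statistic.

A band area is the trapezoidal integral of the spectrum *above the
chord* joining the two window bounds — the local linear background
subtraction that suppresses the residual water combination band under
the silent region. Areas can be negative where only noise is present.

Tag abundances are made comparable across cells by dividing by the mean
area of the DNA backbone band (789 +- 15 cm^-1) over the cell's nuclear
pixels, and compressed for display with the arsinh transform, which
unlike a logarithm is defined for negative ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .containers import (
    CLASS_NAMES,
    CLASS_NUCLEUS,
    HyperspectralCube,
    Spectrum,
    validate_class_map,
)
from .errors import AxisError

#: The ubiquitous half-width of the integration windows.
DEFAULT_HALF_WIDTH = 15.0

#: Canonical windows (cm^-1): nitrile drug tag, alkyne lipid tag, DNA reference.
DRUG_BAND_CENTER = 2223.0
ALKYNE_BAND_CENTER = 2115.0
DNA_BAND_CENTER = 789.0


class BandWindow(BaseModel):
    """An integration window ``center +- half_width`` in cm^-1."""

    center: float
    half_width: float = Field(default=DEFAULT_HALF_WIDTH, gt=0)

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width


@dataclass(frozen=True)
class AreaMap:
    """Per-pixel band areas (counts * cm^-1), possibly normalized."""

    values: np.ndarray  # (H, W)
    window: BandWindow
    normalized: bool = False
    reference_value: Optional[float] = None  # mean nuclear DNA area when normalized


def _window_slice(axis: np.ndarray, window: BandWindow) -> tuple[int, int]:
    """Snap the window bounds to the nearest on-grid channels."""
    axis = np.asarray(axis, dtype=float)
    if window.lo < axis[0] - 1e-9 or window.hi > axis[-1] + 1e-9:
        raise AxisError(
            f"window {window.lo:g}..{window.hi:g} cm^-1 outside axis "
            f"{axis[0]:g}..{axis[-1]:g} cm^-1"
        )
    i0 = int(np.argmin(np.abs(axis - window.lo)))
    i1 = int(np.argmin(np.abs(axis - window.hi)))
    if i1 - i0 < 2:
        raise AxisError(
            f"window {window.lo:g}..{window.hi:g} cm^-1 covers fewer than 3 channels"
        )
    return i0, i1


def band_area(values: np.ndarray, axis: np.ndarray, window: BandWindow) -> np.ndarray:
    """Trapezoid-minus-chord band area; works on stacked spectra (..., K).

    Linear in the spectrum and exactly invariant to adding any affine
    function of wavenumber (the chord absorbs it).
    """
    i0, i1 = _window_slice(axis, window)
    x = np.asarray(axis, dtype=float)[i0 : i1 + 1]
    y = np.asarray(values, dtype=float)[..., i0 : i1 + 1]
    frac = (x - x[0]) / (x[-1] - x[0])
    chord = y[..., :1] * (1.0 - frac) + y[..., -1:] * frac
    return np.trapezoid(y - chord, x, axis=-1)


def band_area_spectrum(spectrum: Spectrum, window: BandWindow) -> float:
    return float(band_area(spectrum.intensities, spectrum.wavenumbers, window))


def area_map(cube: HyperspectralCube, window: BandWindow) -> AreaMap:
    """Band area per pixel."""
    return AreaMap(
        values=band_area(cube.intensities, cube.wavenumbers, window), window=window
    )


def nuclear_reference(area_map_789: AreaMap, class_map: np.ndarray) -> float:
    """Mean DNA-band area over the nucleus pixels (the A-bar_nuc reference)."""
    labels = validate_class_map(class_map)
    sel = labels == CLASS_NUCLEUS
    if not sel.any():
        raise ValueError("class map contains no nucleus pixels (label 3)")
    ref = float(area_map_789.values[sel].mean())
    if ref <= 0:
        raise ValueError(
            f"nuclear DNA reference is non-positive ({ref:g}); unusable for normalization"
        )
    return ref


def normalize_map(amap: AreaMap, reference: float) -> AreaMap:
    """Divide every pixel by the nuclear reference; signs are preserved."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference:g}")
    return AreaMap(
        values=amap.values / reference,
        window=amap.window,
        normalized=True,
        reference_value=reference,
    )


def arsinh_transform(values) -> np.ndarray:
    """Elementwise arsinh(x) = ln(x + sqrt(x^2 + 1)); odd and monotone."""
    return np.arcsinh(np.asarray(values, dtype=float))


def compartment_distributions(
    amap: AreaMap, class_map: np.ndarray, cell_mask: np.ndarray
) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Partition map values by compartment within the cell mask.

    Returns the raw per-class value collections plus a summary table with
    per-class pixel count, mean, SD and standard error. Empty classes
    yield empty collections, not errors.
    """
    labels = validate_class_map(class_map)
    mask = np.asarray(cell_mask, dtype=bool)
    if labels.shape != amap.values.shape or mask.shape != amap.values.shape:
        raise ValueError("class map / cell mask shape does not match the area map")
    collections: dict[int, np.ndarray] = {}
    rows = []
    for label, name in CLASS_NAMES.items():
        values = amap.values[(labels == label) & mask]
        collections[label] = values
        n = values.size
        mean = float(values.mean()) if n else np.nan
        sd = float(values.std(ddof=1)) if n > 1 else np.nan
        rows.append(
            {
                "class": label,
                "name": name,
                "n": n,
                "mean": mean,
                "sd": sd,
                "se": sd / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return collections, pd.DataFrame(rows)
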