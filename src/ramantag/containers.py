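"""Core data containers for hyperspectral Raman analysis.

Every stage of the pipeline passes these objects around: a
:class:`Spectrum` is one intensity trace on a wavenumber axis, a
:class:`HyperspectralCube` is an H x W grid of such spectra sharing one
axis, and compartment segmentations are integer ``ClassMap`` arrays with
the label convention

    1 = background, 2 = cellular matrix, 3 = nucleus, 4 = lipid droplet.

Pixel coordinates are 0-based, row-major, origin top-left throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

#: Compartment label codes shared by every module.
CLASS_BACKGROUND = 1
CLASS_MATRIX = 2
CLASS_NUCLEUS = 3
CLASS_DROPLET = 4

CLASS_NAMES = {
    CLASS_BACKGROUND: "background",
    CLASS_MATRIX: "matrix",
    CLASS_NUCLEUS: "nucleus",
    CLASS_DROPLET: "droplet",
}

VALID_CLASS_LABELS = frozenset(CLASS_NAMES)


def as_wavenumber_axis(values) -> np.ndarray:
    """Validate and return a wavenumber axis (cm^-1).

    The axis must be 1-D, finite and strictly increasing; the first
    offending channel index is named in the error.
    """
    axis = np.asarray(values, dtype=float)
    if axis.ndim != 1 or axis.size == 0:
        raise FormatError("wavenumber axis must be a non-empty 1-D array")
    if not np.all(np.isfinite(axis)):
        bad = int(np.flatnonzero(~np.isfinite(axis))[0])
        raise FormatError(f"non-finite wavenumber at channel {bad}")
    steps = np.diff(axis)
    if np.any(steps <= 0):
        bad = int(np.flatnonzero(steps <= 0)[0]) + 1
        if axis[bad] == axis[bad - 1]:
            raise FormatError(
                f"duplicated wavenumber {axis[bad]:g} at channel {bad}"
            )
        raise FormatError(
            f"wavenumber axis not strictly increasing at channel {bad}"
        )
    return axis


@dataclass(frozen=True)
class Spectrum:
    """A single intensity trace on a wavenumber axis.

    Intensities are detector counts (arbitrary units); negative values
    are legal — background-corrected band areas can dip below zero where
    only noise is present.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "wavenumbers", as_wavenumber_axis(self.wavenumbers))
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != self.wavenumbers.shape:
            raise FormatError(
                f"intensity length {y.shape} does not match axis length "
                f"{self.wavenumbers.shape}"
            )
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise FormatError(f"non-finite intensity at channel {bad}")
        object.__setattr__(self, "intensities", y)

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    def max_normalized(self) -> "Spectrum":
        """Scale so the maximum intensity equals 1 (display convention)."""
        top = float(self.intensities.max())
        if top <= 0:
            raise ValueError("cannot max-normalize a spectrum with max <= 0")
        return Spectrum(self.wavenumbers, self.intensities / top)


@dataclass(frozen=True)
class HyperspectralCube:
    """An H x W image whose every pixel holds a full Raman spectrum.

    ``intensities`` has shape (rows, cols, channels); all pixels share
    ``wavenumbers``. ``pixel_size`` is the lateral sampling in µm.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    pixel_size: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "wavenumbers", as_wavenumber_axis(self.wavenumbers))
        data = np.asarray(self.intensities, dtype=float)
        if data.ndim != 3:
            raise FormatError("cube intensities must have shape (rows, cols, channels)")
        if data.shape[-1] != self.wavenumbers.size:
            raise FormatError(
                f"cube has {data.shape[-1]} channels but axis has "
                f"{self.wavenumbers.size}"
            )
        if self.pixel_size <= 0:
            raise FormatError("pixel_size must be positive")
        object.__setattr__(self, "intensities", data)

    @property
    def rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def cols(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.intensities[row, col])

    def mean_spectrum(self, mask: np.ndarray | None = None) -> Spectrum:
        """Mean spectrum over all pixels, or over a boolean mask."""
        if mask is None:
            mean = self.intensities.reshape(-1, self.n_channels).mean(axis=0)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.intensities.shape[:2]:
                raise FormatError("mask shape does not match cube")
            if not mask.any():
                raise ValueError("mask selects no pixels")
            mean = self.intensities[mask].mean(axis=0)
        return Spectrum(self.wavenumbers, mean)


def validate_class_map(arr, allow_unlabeled: bool = False) -> np.ndarray:
    """Validate a compartment label image.

    Labels must lie in {1, 2, 3, 4}; with ``allow_unlabeled`` the value 0
    (unannotated pixel) is tolerated, which is the annotation convention.
    """
    labels = np.asarray(arr)
    if labels.ndim != 2:
        raise FormatError("class map must be a 2-D label image")
    labels = labels.astype(np.int64)
    allowed = VALID_CLASS_LABELS | ({0} if allow_unlabeled else set())
    present = set(np.unique(labels).tolist())
    bad = present - allowed
    if bad:
        raise FormatError(
            f"class map contains invalid label(s) {sorted(bad)}; "
            f"allowed values are {sorted(allowed)}"
        )
    return labels


def validate_cell_mask(arr) -> np.ndarray:
    mask = np.asarray(arr)
    if mask.ndim != 2:
        raise FormatError("cell mask must be a 2-D boolean image")
    return mask.astype(bool)
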