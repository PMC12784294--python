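"""Readers and writers for the package's data objects.

Cubes travel in a self-describing HDF5 container (lossless round-trip),
spectra and DFT mode tables as two-column delimited text, and label
maps/masks as single-channel 8-bit TIFF or PNG images.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .containers import (
    HyperspectralCube,
    Spectrum,
    as_wavenumber_axis,
    validate_cell_mask,
    validate_class_map,
)
from .errors import FormatError

_CUBE_AXIS = "wavenumbers"
_CUBE_DATA = "intensities"


def write_cube(path, cube: HyperspectralCube) -> None:
    """Write a cube to an HDF5 container (axis, intensities, pixel size)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset(_CUBE_AXIS, data=cube.wavenumbers)
        fh.create_dataset(_CUBE_DATA, data=cube.intensities)
        fh.attrs["pixel_size_um"] = float(cube.pixel_size)


def read_cube(path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`; exact round-trip."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 cube container ({exc})")
    with fh:
        for name in (_CUBE_AXIS, _CUBE_DATA):
            if name not in fh:
                raise FormatError(f"{path}: missing dataset '{name}'")
        axis = np.asarray(fh[_CUBE_AXIS])
        data = np.asarray(fh[_CUBE_DATA])
        pixel_size = float(fh.attrs.get("pixel_size_um", 0.5))
    return HyperspectralCube(as_wavenumber_axis(axis), data, pixel_size)


def write_spectrum(path, spectrum: Spectrum, header: bool = True) -> None:
    """Write a spectrum as two-column TSV (wavenumber, intensity)."""
    with open(path, "w") as fh:
        if header:
            fh.write("wavenumber_cm-1\tintensity\n")
        for x, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{x:.10g}\t{y:.10g}\n")


def _parse_two_columns(path, skip_header: bool):
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split()
            if skip_header and lineno == 1:
                try:
                    [float(v) for v in fields]
                except ValueError:
                    continue  # flagged header line tolerated
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two columns, got {len(fields)}"
                )
            try:
                rows.append((float(fields[0]), float(fields[1])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value in {fields[:2]}")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.array(rows, dtype=float)


def read_spectrum(path, header: bool = True) -> Spectrum:
    """Read a two-column (wavenumber, intensity) text file.

    With ``header`` a single non-numeric leading line is tolerated.
    """
    table = _parse_two_columns(path, skip_header=header)
    return Spectrum(table[:, 0], table[:, 1])


def write_mask(path, arr: np.ndarray) -> None:
    """Write a ClassMap / CellMask / truth map as an 8-bit image."""
    img = np.asarray(arr)
    if img.dtype == bool:
        img = img.astype(np.uint8)
    if img.max(initial=0) > 255:
        img = img.astype(np.uint16)
    else:
        img = img.astype(np.uint8)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def _read_label_image(path) -> np.ndarray:
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel label image, got shape {img.shape}"
        )
    return np.asarray(img)


def read_class_map(path, allow_unlabeled: bool = False) -> np.ndarray:
    """Read a compartment label image; values outside {0..4} are rejected."""
    img = _read_label_image(path)
    try:
        return validate_class_map(img, allow_unlabeled=True if allow_unlabeled else False)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}")


def read_cell_mask(path) -> np.ndarray:
    """Read a binary mask image (any nonzero pixel is True)."""
    return validate_cell_mask(_read_label_image(path) != 0)


def read_activity_table(path):
    """Read a DFT mode table: columns (frequency cm^-1, Raman activity).

    Returns a :class:`ramantag.dft.RamanModeTable` with modes sorted by
    frequency. Negative frequencies or activities are rejected.
    """
    from .dft import RamanModeTable

    table = _parse_two_columns(path, skip_header=True)
    freqs, acts = table[:, 0], table[:, 1]
    if np.any(freqs <= 0):
        bad = int(np.flatnonzero(freqs <= 0)[0])
        raise FormatError(f"{path}: non-positive mode frequency at row {bad}")
    if np.any(acts < 0):
        bad = int(np.flatnonzero(acts < 0)[0])
        raise FormatError(f"{path}: negative Raman activity at row {bad}")
    order = np.argsort(freqs, kind="stable")
    return RamanModeTable(frequencies=freqs[order], activities=acts[order])


def acetaminophen_reference_path() -> Path:
    """Path of the shipped 4-acetaminophen calibration band table."""
    return Path(__file__).parent / "data" / "acetaminophen_reference.tsv"
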