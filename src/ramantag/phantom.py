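"""Synthetic cell phantoms with ground truth.

A phantom emulates a hyperspectral Raman map of a single macrophage-like
cell: an elliptical cell body on empty background, an elliptical nucleus,
and circular lipid droplets in the cytoplasm. Each compartment carries a
dictionary of Lorentzian Raman bands (the nucleus includes the DNA
backbone band near 789 cm^-1, droplets the lipid CH2 bands near
2850/1447 cm^-1). On top of the endogenous bands sit the two
bioorthogonal tag band sets — the nitrile-tagged drug (2223 cm^-1 with
1618/1510/1255 cm^-1 companions) and the alkyne-tagged fatty acid
(2115 cm^-1) — scaled per compartment by the true tag loadings that the
pipeline later has to recover. A broad water combination band underlies
the silent region, a low-order polynomial baseline underlies everything,
and i.i.d. Gaussian noise plus optional single-channel cosmic-ray spikes
complete the measurement model.

Defaults describe a treated M1-like cell: drug strongly enriched in lipid
droplets (loading 1.0) over matrix (0.15) and nucleus (0.10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .containers import (
    CLASS_BACKGROUND,
    CLASS_DROPLET,
    CLASS_MATRIX,
    CLASS_NUCLEUS,
    HyperspectralCube,
    VALID_CLASS_LABELS,
)
from .errors import GeometryError


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-peak-height Lorentzian profile (FWHM parameterization)."""
    half = fwhm / 2.0
    return half**2 / ((np.asarray(x, dtype=float) - center) ** 2 + half**2)


class Band(BaseModel):
    """One Lorentzian band: center (cm^-1), FWHM (cm^-1), peak height (counts)."""

    center: float
    fwhm: float = Field(gt=0)
    amplitude: float = Field(ge=0)

    @model_validator(mode="before")
    @classmethod
    def _from_sequence(cls, value):
        if isinstance(value, (tuple, list)):
            return dict(zip(("center", "fwhm", "amplitude"), value))
        return value


class Ellipse(BaseModel):
    """Axis-aligned ellipse in pixel coordinates (row/col center, semi-axes)."""

    row: float
    col: float
    semi_row: float = Field(gt=0)
    semi_col: float = Field(gt=0)

    @model_validator(mode="before")
    @classmethod
    def _from_sequence(cls, value):
        if isinstance(value, (tuple, list)):
            return dict(zip(("row", "col", "semi_row", "semi_col"), value))
        return value

    def metric(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """<=1 inside the ellipse, >1 outside."""
        return ((rows - self.row) / self.semi_row) ** 2 + (
            (cols - self.col) / self.semi_col
        ) ** 2


def _default_band_dictionary() -> dict[int, list[Band]]:
    return {
        CLASS_BACKGROUND: [],
        CLASS_MATRIX: [
            Band(center=1100, fwhm=20, amplitude=40),
            Band(center=1267, fwhm=20, amplitude=50),
            Band(center=1447, fwhm=16, amplitude=80),
            Band(center=1661, fwhm=18, amplitude=90),
            Band(center=2940, fwhm=30, amplitude=150),
        ],
        CLASS_NUCLEUS: [
            Band(center=789, fwhm=14, amplitude=120),
            Band(center=1100, fwhm=20, amplitude=60),
            Band(center=1342, fwhm=18, amplitude=70),
            Band(center=1447, fwhm=16, amplitude=60),
            Band(center=1661, fwhm=18, amplitude=70),
            Band(center=2940, fwhm=30, amplitude=120),
        ],
        CLASS_DROPLET: [
            Band(center=1267, fwhm=18, amplitude=80),
            Band(center=1447, fwhm=16, amplitude=160),
            Band(center=1661, fwhm=18, amplitude=60),
            Band(center=2850, fwhm=24, amplitude=300),
            Band(center=2940, fwhm=30, amplitude=180),
        ],
    }


def _default_drug_bands() -> list[Band]:
    # nitrile stretch plus the aromatic companions; relative heights
    # 1.0 : 0.35 : 0.3 : 0.15 at a base peak height of 80 counts.
    return [
        Band(center=2223, fwhm=12, amplitude=80),
        Band(center=1618, fwhm=14, amplitude=28),
        Band(center=1510, fwhm=14, amplitude=24),
        Band(center=1255, fwhm=14, amplitude=12),
    ]


def _default_odya_bands() -> list[Band]:
    return [Band(center=2115, fwhm=14, amplitude=100)]


class PhantomSpec(BaseModel):
    """Full description of a synthetic cell phantom.

    Identical (spec, seed) pairs yield bit-identical cubes.
    """

    grid_rows: int = Field(default=64, ge=8)
    grid_cols: int = Field(default=64, ge=8)
    pixel_size: float = Field(default=0.5, gt=0)

    cell_ellipse: Ellipse = Ellipse(row=32, col=32, semi_row=26, semi_col=28)
    nucleus_ellipse: Ellipse = Ellipse(row=32, col=29, semi_row=10, semi_col=11)
    droplet_count: int = Field(default=8, ge=0)
    droplet_radius_px: float = Field(default=3.0, ge=1)

    band_dictionary: dict[int, list[Band]] = Field(default_factory=_default_band_dictionary)
    drug_bands: list[Band] = Field(default_factory=_default_drug_bands)
    odya_bands: list[Band] = Field(default_factory=_default_odya_bands)
    drug_loading: dict[int, float] = Field(
        default_factory=lambda: {1: 0.0, 2: 0.15, 3: 0.10, 4: 1.0}
    )
    odya_loading: dict[int, float] = Field(
        default_factory=lambda: {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    )
    #: Optional perinuclear ring of extra drug (width in px outward from
    #: the nucleus boundary); 0 disables it.
    ring_width_px: float = Field(default=0.0, ge=0)
    ring_drug_loading: float = Field(default=0.0, ge=0)

    water_band: Band = Band(center=2150, fwhm=400, amplitude=50)
    baseline_poly: list[float] = Field(default_factory=lambda: [120.0, 0.01])
    noise_sd: float = Field(default=1.5, ge=0)
    spike_rate: float = Field(default=0.0, ge=0, le=1)
    spike_amplitude: float = Field(default=0.0, ge=0)

    wn_start: float = 550.0
    wn_stop: float = 3150.0
    wn_step: float = Field(default=2.0, gt=0)
    seed: int = 0

    @field_validator("band_dictionary", "drug_loading", "odya_loading")
    @classmethod
    def _class_keys(cls, value):
        bad = set(value) - VALID_CLASS_LABELS
        if bad:
            raise ValueError(f"invalid compartment label(s) {sorted(bad)}")
        return value

    @field_validator("drug_loading", "odya_loading")
    @classmethod
    def _nonnegative(cls, value):
        for k, v in value.items():
            if v < 0:
                raise ValueError(f"loading for class {k} must be >= 0")
        return value

    @model_validator(mode="after")
    def _geometry(self):
        if self.wn_start >= self.wn_stop:
            raise ValueError("wn_start must be below wn_stop")
        cell, nuc = self.cell_ellipse, self.nucleus_ellipse
        theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        rr = nuc.row + nuc.semi_row * np.cos(theta)
        cc = nuc.col + nuc.semi_col * np.sin(theta)
        if np.any(cell.metric(rr, cc) >= 1.0):
            raise GeometryError("nucleus ellipse is not strictly inside the cell ellipse")
        return self

    def wavenumber_axis(self) -> np.ndarray:
        n = int(round((self.wn_stop - self.wn_start) / self.wn_step)) + 1
        return self.wn_start + self.wn_step * np.arange(n)

    # -- plain-text (TOML) serialization -------------------------------

    def to_toml(self, path) -> None:
        from . import _toml

        _toml.dump(self.model_dump(), path)

    @classmethod
    def from_toml(cls, path) -> "PhantomSpec":
        from . import _toml

        return cls.model_validate(_toml.load(path))


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a phantom cube."""

    class_map: np.ndarray  # (H, W) labels in {1..4}
    drug_map: np.ndarray  # (H, W) true drug loading, >= 0
    odya_map: np.ndarray  # (H, W) true alkyne-lipid loading, >= 0
    ring_mask: np.ndarray  # (H, W) bool, perinuclear extra-drug region
    spike_positions: Optional[np.ndarray] = None  # (n, 3) row, col, channel


def _bands_spectrum(bands: list[Band], axis: np.ndarray) -> np.ndarray:
    out = np.zeros_like(axis)
    for band in bands:
        out += band.amplitude * lorentzian(axis, band.center, band.fwhm)
    return out


def _place_droplets(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded rejection sampling of droplet centers inside the cell,
    outside the nucleus, non-overlapping."""
    rad = spec.droplet_radius_px
    cell, nuc = spec.cell_ellipse, spec.nucleus_ellipse
    inner = Ellipse(
        row=cell.row,
        col=cell.col,
        semi_row=max(cell.semi_row - rad - 0.5, 1e-6),
        semi_col=max(cell.semi_col - rad - 0.5, 1e-6),
    )
    outer_nuc = Ellipse(
        row=nuc.row, col=nuc.col, semi_row=nuc.semi_row + rad, semi_col=nuc.semi_col + rad
    )
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < spec.droplet_count:
        tries += 1
        if tries > 20000:
            raise GeometryError(
                f"could not place {spec.droplet_count} droplets of radius "
                f"{rad} inside the cell and outside the nucleus"
            )
        r = rng.uniform(0, spec.grid_rows)
        c = rng.uniform(0, spec.grid_cols)
        if inner.metric(r, c) > 1.0 or outer_nuc.metric(r, c) <= 1.0:
            continue
        if any((r - r0) ** 2 + (c - c0) ** 2 < (2 * rad + 1) ** 2 for r0, c0 in centers):
            continue
        centers.append((r, c))
    return np.array(centers, dtype=float).reshape(-1, 2)


def _build_class_map(spec: PhantomSpec, rng: np.random.Generator):
    rows, cols = np.mgrid[0 : spec.grid_rows, 0 : spec.grid_cols]
    class_map = np.full((spec.grid_rows, spec.grid_cols), CLASS_BACKGROUND, dtype=np.int64)
    class_map[spec.cell_ellipse.metric(rows, cols) <= 1.0] = CLASS_MATRIX
    class_map[spec.nucleus_ellipse.metric(rows, cols) <= 1.0] = CLASS_NUCLEUS
    for r0, c0 in _place_droplets(spec, rng):
        disc = (rows - r0) ** 2 + (cols - c0) ** 2 <= spec.droplet_radius_px**2
        class_map[disc] = CLASS_DROPLET

    ring_mask = np.zeros_like(class_map, dtype=bool)
    if spec.ring_width_px > 0:
        nuc = spec.nucleus_ellipse
        grown = Ellipse(
            row=nuc.row,
            col=nuc.col,
            semi_row=nuc.semi_row + spec.ring_width_px,
            semi_col=nuc.semi_col + spec.ring_width_px,
        )
        ring_mask = (grown.metric(rows, cols) <= 1.0) & (class_map == CLASS_MATRIX)
    return class_map, ring_mask


def inject_spikes(
    intensities: np.ndarray, rate: float, amplitude: float, seed: int | np.random.Generator
):
    """Add single-channel cosmic-ray spikes at seeded positions.

    Exactly ``round(rate * size)`` entries get ``+amplitude``; the spiked
    array and the (row, col, channel) position list are returned so
    despiking tests can check flags against an exact oracle.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"spike rate must be in [0, 1], got {rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.array(intensities, dtype=float)
    count = int(round(rate * data.size))
    if count == 0:
        return data, np.empty((0, 3), dtype=np.int64)
    flat = rng.choice(data.size, size=count, replace=False)
    flat.sort()
    data.reshape(-1)[flat] += amplitude
    positions = np.column_stack(np.unravel_index(flat, data.shape)).astype(np.int64)
    return data, positions


def make_phantom(spec: PhantomSpec) -> tuple[HyperspectralCube, PhantomTruth]:
    """Render a phantom cube and its ground truth.

    The cube is the sum of per-compartment endogenous bands, the drug and
    alkyne tag band sets scaled by the true per-pixel loadings, the broad
    water combination band, the polynomial baseline, Gaussian noise, and
    optional spikes. Deterministic under (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    axis = spec.wavenumber_axis()
    class_map, ring_mask = _build_class_map(spec, rng)

    drug_map = np.zeros(class_map.shape)
    odya_map = np.zeros(class_map.shape)
    for label in VALID_CLASS_LABELS:
        sel = class_map == label
        drug_map[sel] = spec.drug_loading.get(label, 0.0)
        odya_map[sel] = spec.odya_loading.get(label, 0.0)
    if spec.ring_width_px > 0:
        drug_map[ring_mask] = spec.ring_drug_loading

    base = np.polynomial.polynomial.polyval(axis, spec.baseline_poly)
    base = base + spec.water_band.amplitude * lorentzian(
        axis, spec.water_band.center, spec.water_band.fwhm
    )
    class_spectra = {
        label: _bands_spectrum(spec.band_dictionary.get(label, []), axis)
        for label in VALID_CLASS_LABELS
    }
    drug_unit = _bands_spectrum(spec.drug_bands, axis)
    odya_unit = _bands_spectrum(spec.odya_bands, axis)

    cube = np.broadcast_to(base, (spec.grid_rows, spec.grid_cols, axis.size)).copy()
    for label, spectrum in class_spectra.items():
        cube[class_map == label] += spectrum
    cube += drug_map[..., None] * drug_unit
    cube += odya_map[..., None] * odya_unit

    if spec.noise_sd > 0:
        cube += rng.normal(0.0, spec.noise_sd, size=cube.shape)

    spike_positions = None
    if spec.spike_rate > 0 and spec.spike_amplitude > 0:
        cube, spike_positions = inject_spikes(
            cube, spec.spike_rate, spec.spike_amplitude, rng
        )

    truth = PhantomTruth(
        class_map=class_map,
        drug_map=drug_map,
        odya_map=odya_map,
        ring_mask=ring_mask,
        spike_positions=spike_positions,
    )
    return HyperspectralCube(axis, cube, spec.pixel_size), truth
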