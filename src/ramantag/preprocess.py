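"""Spectral pre-processing chain.

Order of operations per pixel, matching the acquisition pipeline the
package models: cosmic-ray despiking (modified z-scores of first
differences, Whittaker–Hayes style), sectioned SNIP background
correction with a cross-faded merge, wavenumber calibration against a
reference substance, and linear resampling onto a uniform grid
(default 600–3050 cm^-1 in 2 cm^-1 steps, 1226 channels).

All numerical cores accept stacked spectra of shape (..., K) so cubes
are processed without Python-level per-pixel loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.interpolate import interp1d

from .containers import HyperspectralCube, Spectrum
from .errors import AxisError

log = logging.getLogger(__name__)

#: Consistency constant relating MAD to the SD of a normal distribution.
_MAD_SCALE = 0.6745

#: Half-width (channels) of the neighborhood used to replace a flagged channel.
_REPLACE_WINDOW = 3

DEFAULT_SPIKE_THRESHOLD = 37.0


class SnipSection(BaseModel):
    """One SNIP background-correction section: bounds (cm^-1) + iterations."""

    lo: float
    hi: float
    iterations: int = Field(ge=1)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.lo < self.hi:
            raise ValueError(f"section bounds must satisfy lo < hi, got {self.lo}..{self.hi}")
        return self


def default_snip_sections() -> list[SnipSection]:
    """The three-section scheme: a 100-iteration fingerprint section, a
    gentle 7-iteration silent-region section (protects narrow tag bands
    while removing the broad water background), and a 100-iteration
    high-wavenumber section; neighbors overlap for cross-fading."""
    return [
        SnipSection(lo=2600, hi=3150, iterations=100),
        SnipSection(lo=1800, hi=2800, iterations=7),
        SnipSection(lo=550, hi=1900, iterations=100),
    ]


class ResampleGrid(BaseModel):
    start: float = 600.0
    stop: float = 3050.0
    step: float = Field(default=2.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.start >= self.stop:
            raise ValueError("grid start must be below stop")
        return self

    def axis(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


class PreprocessConfig(BaseModel):
    spike_threshold: float = DEFAULT_SPIKE_THRESHOLD
    sections: list[SnipSection] = Field(default_factory=default_snip_sections)
    grid: ResampleGrid = ResampleGrid()
    #: (reference, measured) calibrant band pairs; empty list = no shift.
    calibration_pairs: list[tuple[float, float]] = Field(default_factory=list)


@dataclass
class PreprocessReport:
    """Per-stage summary returned alongside the processed cube."""

    spike_flags: np.ndarray  # bool, shape of the *input* cube
    n_spike_flags: int
    calibration_shift: float
    sections: list[SnipSection] = field(default_factory=list)


# ---------------------------------------------------------------------------
# despiking


def despike(values: np.ndarray, threshold: float = DEFAULT_SPIKE_THRESHOLD):
    """Flag and repair single-channel spikes.

    Modified z-scores are computed on the first differences
    ``d_i = x_i - x_{i-1}`` as ``0.6745 * (d - median(d)) / MAD(d)``
    per spectrum; channel ``i`` (i >= 1) owns ``d_i`` and is flagged when
    ``|z_i|`` exceeds the threshold. Channel 0 owns no difference and is
    flagged only on the one-sided signature of a leading-edge spike
    (``|z_1|`` over threshold without the sign-flipped partner ``z_2``).
    Flagged channels are replaced by the mean of unflagged channels
    within +-3 channels. A spectrum with MAD = 0 (constant data) gets no
    flags.

    Parameters
    ----------
    values : array (..., K), K >= 3
    threshold : modified-z cutoff (default 37).

    Returns
    -------
    (corrected, flags) with ``flags`` boolean of the same shape.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("despiking needs at least 3 channels")
    d = np.diff(x, axis=-1)
    med = np.median(d, axis=-1, keepdims=True)
    mad = np.median(np.abs(d - med), axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = _MAD_SCALE * (d - med) / mad
    z = np.where(mad > 0, z, 0.0)

    flags = np.zeros(x.shape, dtype=bool)
    flags[..., 1:] = np.abs(z) > threshold
    # channel 0 owns no difference; a spike there leaves the one-sided
    # signature |z_1| large with |z_2| ordinary (an interior spike flips
    # sign across the pair d_i, d_{i+1}); flag it so the repair window
    # never ingests an unrepaired leading spike.
    flags[..., 0] = (np.abs(z[..., 0]) > threshold) & ~(np.abs(z[..., 1]) > threshold)

    corrected = x.copy()
    if flags.any():
        flat_x = corrected.reshape(-1, x.shape[-1])
        flat_f = flags.reshape(-1, x.shape[-1])
        for row in np.flatnonzero(flat_f.any(axis=-1)):
            _replace_flagged(flat_x[row], flat_f[row])
        corrected = flat_x.reshape(x.shape)
    return corrected, flags


def _replace_flagged(x: np.ndarray, flagged: np.ndarray) -> None:
    """In-place neighborhood-mean replacement of flagged channels."""
    k = x.size
    good_values = x.copy()
    for i in np.flatnonzero(flagged):
        width = _REPLACE_WINDOW
        while True:
            lo, hi = max(0, i - width), min(k, i + width + 1)
            window = np.arange(lo, hi)
            good = window[~flagged[window]]
            if good.size:
                x[i] = good_values[good].mean()
                break
            width += _REPLACE_WINDOW  # degenerate: widen until an unflagged channel exists
            if width > k:
                break  # all channels flagged; leave untouched


def despike_spectrum(
    spectrum: Spectrum, threshold: float = DEFAULT_SPIKE_THRESHOLD
) -> tuple[Spectrum, np.ndarray]:
    corrected, flags = despike(spectrum.intensities, threshold)
    return Spectrum(spectrum.wavenumbers, corrected), np.flatnonzero(flags)


# ---------------------------------------------------------------------------
# SNIP background


def _section_slice(axis: np.ndarray, lo: float, hi: float) -> slice:
    if lo < axis[0] - 1e-9 or hi > axis[-1] + 1e-9:
        raise AxisError(
            f"section {lo}..{hi} cm^-1 falls outside the axis "
            f"{axis[0]:g}..{axis[-1]:g} cm^-1"
        )
    i0 = int(np.searchsorted(axis, lo - 1e-9, side="left"))
    i1 = int(np.searchsorted(axis, hi + 1e-9, side="right"))
    return slice(i0, i1)


def snip_baseline(values: np.ndarray, iterations: int) -> np.ndarray:
    """Plain SNIP baseline on a contiguous sample block.

    Iterative clipping ``b_i <- min(b_i, (b_{i-p} + b_{i+p}) / 2)`` with
    the half-window ``p`` increasing 1..iterations; out-of-range
    neighbors are clamped to the edges. The result never exceeds the
    input at any channel.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[-1]
    if n <= 2 * iterations:
        raise ValueError(
            f"SNIP with {iterations} iterations needs more than {2 * iterations} "
            f"samples, got {n}"
        )
    b = y.copy()
    idx = np.arange(n)
    for p in range(1, iterations + 1):
        left = b[..., np.clip(idx - p, 0, n - 1)]
        right = b[..., np.clip(idx + p, 0, n - 1)]
        b = np.minimum(b, 0.5 * (left + right))
    return b


def snip_baseline_section(
    spectrum: Spectrum, section: SnipSection
) -> tuple[np.ndarray, slice]:
    """Baseline estimate restricted to one section; returns (baseline, slice)."""
    sl = _section_slice(spectrum.wavenumbers, section.lo, section.hi)
    return snip_baseline(spectrum.intensities[sl], section.iterations), sl


def sectioned_correct(
    values: np.ndarray, axis: np.ndarray, sections: list[SnipSection] | None = None
) -> np.ndarray:
    """Background-correct by per-section SNIP and cross-faded merge.

    Inside a single section the correction is ``y - baseline``; where two
    sections overlap their corrections are blended with a linear
    cross-fade across the overlap; channels outside every section pass
    through unchanged.
    """
    if sections is None:
        sections = default_snip_sections()
    x = np.asarray(values, dtype=float)
    weighted = np.zeros_like(x)
    weights = np.zeros_like(axis)
    cover = np.zeros(axis.size, dtype=np.int64)
    corrections = []
    for section in sections:
        sl = _section_slice(axis, section.lo, section.hi)
        corr = x[..., sl] - snip_baseline(x[..., sl], section.iterations)
        # triangular weight: 0 at the section edges, maximal in the middle;
        # in an overlap whose ends coincide with the two sections' edges this
        # normalizes to an exactly linear cross-fade.
        w = np.minimum(axis[sl] - section.lo, section.hi - axis[sl])
        weighted[..., sl] += w * corr
        weights[sl] += w
        cover[sl] += 1
        corrections.append((sl, corr))

    out = x.copy()
    covered = cover > 0
    safe = covered & (weights > 0)
    out[..., safe] = weighted[..., safe] / weights[safe]
    # edge channels covered by section(s) with zero triangular weight:
    degenerate = covered & (weights == 0)
    if degenerate.any():
        acc = np.zeros_like(x)
        for sl, corr in corrections:
            block = np.zeros(axis.size, dtype=bool)
            block[sl] = True
            pick = degenerate & block
            if pick.any():
                local = pick[sl]
                acc[..., pick] += corr[..., local]
        out[..., degenerate] = acc[..., degenerate] / cover[degenerate]
    return out


# ---------------------------------------------------------------------------
# calibration and resampling


class CalibrationTable(BaseModel):
    """(reference, measured) calibrant band position pairs in cm^-1."""

    pairs: list[tuple[float, float]] = Field(min_length=1)

    @model_validator(mode="after")
    def _increasing_refs(self):
        refs = [p[0] for p in self.pairs]
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise ValueError("reference positions must be strictly increasing")
        return self

    def shift(self) -> float:
        return float(np.mean([ref - meas for ref, meas in self.pairs]))


def calibrate(axis: np.ndarray, table: CalibrationTable) -> tuple[np.ndarray, float]:
    """Shift the axis by the mean (reference - measured) offset."""
    shift = table.shift()
    return np.asarray(axis, dtype=float) + shift, shift


def resample(
    values: np.ndarray, axis: np.ndarray, grid: ResampleGrid | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto the uniform grid; no extrapolation."""
    grid = grid or ResampleGrid()
    axis = np.asarray(axis, dtype=float)
    if axis[0] > grid.start or axis[-1] < grid.stop:
        raise AxisError(
            f"input axis {axis[0]:g}..{axis[-1]:g} does not cover the target "
            f"grid {grid.start:g}..{grid.stop:g} (no extrapolation)"
        )
    new_axis = grid.axis()
    interp = interp1d(axis, np.asarray(values, dtype=float), axis=-1, assume_sorted=True)
    return interp(new_axis), new_axis


def resample_spectrum(spectrum: Spectrum, grid: ResampleGrid | None = None) -> Spectrum:
    values, axis = resample(spectrum.intensities, spectrum.wavenumbers, grid)
    return Spectrum(axis, values)


# ---------------------------------------------------------------------------
# whole-cube chain


def preprocess_cube(
    cube: HyperspectralCube, config: PreprocessConfig | None = None
) -> tuple[HyperspectralCube, PreprocessReport]:
    """despike -> sectioned SNIP correct -> calibrate -> resample, per pixel."""
    config = config or PreprocessConfig()
    data = cube.intensities
    despiked, flags = despike(data, config.spike_threshold)
    log.info("despike: flagged %d of %d entries", int(flags.sum()), flags.size)

    corrected = sectioned_correct(despiked, cube.wavenumbers, config.sections)

    shift = 0.0
    axis = cube.wavenumbers
    if config.calibration_pairs:
        axis, shift = calibrate(axis, CalibrationTable(pairs=config.calibration_pairs))
        log.info("calibration: applied shift %+.3f cm^-1", shift)

    resampled, new_axis = resample(corrected, axis, config.grid)
    report = PreprocessReport(
        spike_flags=flags,
        n_spike_flags=int(flags.sum()),
        calibration_shift=shift,
        sections=list(config.sections),
    )
    return HyperspectralCube(new_axis, resampled, cube.pixel_size), report
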