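"""Smoothing-spline / second-derivative peak detection.

A degree-4 smoothing spline is fitted to the max-1-normalized spectrum;
band maxima appear as negative local minima of its second derivative.
Detections must clear a height limit (2% of the largest second-
derivative magnitude) and a vertical hysteresis of Delta = 0.01 on the
normalized spectrum, which suppresses noise wiggles. Positions are read
off a 10x-refined evaluation grid of the spline.

The treated-vs-control report lists the bands present in a treated
spectrum with no counterpart in the control within a match tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field
from scipy.interpolate import UnivariateSpline

from .containers import Spectrum

_MAD_SCALE = 0.6745


class PeakFindConfig(BaseModel):
    spline_degree: int = Field(default=4, ge=2, le=5)
    #: Residual budget of the smoothing spline in units of the estimated
    #: noise variance (the scipy ``s`` parameter with 1/sigma weights);
    #: approximately the channel count of the spectra it was tuned on.
    smoothing_factor: float = Field(default=1000.0, ge=0)
    height_fraction: float = Field(default=0.02, gt=0, lt=1)
    delta: float = Field(default=0.01, gt=0)
    refine: int = Field(default=10, ge=1)
    match_tolerance: float = Field(default=10.0, ge=0)


@dataclass(frozen=True)
class Peak:
    position: float  # cm^-1
    curvature: float  # |second derivative| of the spline at the extremum


def _robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD estimate from the MAD of first differences."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / (_MAD_SCALE * np.sqrt(2.0)))


def _passes_hysteresis(values: np.ndarray, idx: int, delta: float) -> bool:
    """The spectrum must recede by >= delta on both sides of the band's
    local maximum before rising back above it.

    The second-derivative extremum of an overlapped band sits slightly
    off the spectrum's local maximum, so the walk first climbs to the
    nearest local max and applies the vertical-hysteresis test there.
    """
    n = values.size
    i = idx
    while 0 < i < n - 1:
        if values[i + 1] > values[i]:
            i += 1
        elif values[i - 1] > values[i]:
            i -= 1
        else:
            break
    peak = values[i]
    for step in (-1, 1):
        j = i + step
        ok = False
        while 0 <= j < n:
            if values[j] <= peak - delta:
                ok = True
                break
            if values[j] > peak:
                break
            j += step
        if not ok:
            return False
    return True


def find_peaks(spectrum: Spectrum, config: PeakFindConfig | None = None) -> list[Peak]:
    """Detect band positions in a spectrum.

    Detected positions are invariant to positive rescaling of the input
    (the spectrum is max-normalized first). A flat spectrum yields an
    empty list.
    """
    config = config or PeakFindConfig()
    x = spectrum.wavenumbers
    if x.size < config.spline_degree + 1:
        raise ValueError(
            f"need at least {config.spline_degree + 1} channels, got {x.size}"
        )
    y = spectrum.intensities
    span = float(y.max() - y.min())
    if span == 0:
        return []
    y = y / float(y.max()) if y.max() > 0 else (y - y.min()) / span

    sigma = _robust_noise_sd(y)
    if sigma > 0:
        spline = UnivariateSpline(
            x, y, w=np.full(x.size, 1.0 / sigma), k=config.spline_degree,
            s=config.smoothing_factor,
        )
    else:
        spline = UnivariateSpline(x, y, k=config.spline_degree, s=0.0)

    xs = np.linspace(x[0], x[-1], x.size * config.refine)
    ys = spline(xs)
    d2 = spline.derivative(2)(xs)

    interior = np.arange(1, xs.size - 1)
    is_min = (d2[interior] < d2[interior - 1]) & (d2[interior] <= d2[interior + 1])
    candidates = interior[is_min & (d2[interior] < 0)]
    if candidates.size == 0:
        return []
    floor = config.height_fraction * float(np.max(np.abs(d2)))
    peaks = [
        Peak(position=float(xs[i]), curvature=float(-d2[i]))
        for i in candidates
        if -d2[i] >= floor and _passes_hysteresis(ys, int(i), config.delta)
    ]
    peaks.sort(key=lambda p: p.position)
    return peaks


def differential_bands(
    treated: Spectrum,
    control: Spectrum,
    config: PeakFindConfig | None = None,
) -> list[Peak]:
    """Bands present in the treated spectrum but absent from the control.

    Both spectra must share one wavenumber axis. A treated peak counts as
    new when no control peak lies within ``config.match_tolerance`` cm^-1
    (default 10; a tolerance of 0 would report every band as new under
    run-to-run jitter, which is why the default is positive).
    """
    config = config or PeakFindConfig()
    if treated.wavenumbers.shape != control.wavenumbers.shape or not np.allclose(
        treated.wavenumbers, control.wavenumbers
    ):
        raise ValueError("treated and control spectra must share a common axis")
    treated_peaks = find_peaks(treated, config)
    control_positions = np.array([p.position for p in find_peaks(control, config)])
    if control_positions.size == 0:
        return treated_peaks
    return [
        p
        for p in treated_peaks
        if np.min(np.abs(control_positions - p.position)) > config.match_tolerance
    ]
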