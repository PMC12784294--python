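"""Two-tag colocalization: scatter assembly, density-based partition,
and pixel back-projection.

Every cell pixel contributes a point (x = normalized nitrile/CN area,
y = normalized alkyne/CC area); pixels with a negative coordinate are
excluded but remembered. Points with a consistent CC/CN ratio lie on a
line through the origin; the partition splits the retained cloud into
four segments by (a) the central line whose slope is the CC/CN ratio at
the density mode and (b) an intensity boundary t0 along that line,
placed just beyond the densest cluster (factor 1.05 by default). The
four segment labels, plus a distinct code for excluded pixels, are
painted back onto the pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .containers import validate_cell_mask
from .quantify import AreaMap

#: Segment codes (and the back-projection image palette).
SEG_LOW_RATIO_LOW_I = 1  # CN-dominated, weak signal
SEG_LOW_RATIO_HIGH_I = 2  # CN-dominated, strong signal
SEG_HIGH_RATIO_LOW_I = 3  # CC-dominated, weak signal
SEG_HIGH_RATIO_HIGH_I = 4  # CC-dominated, strong signal
EXCLUDED_CODE = 5
BACKGROUND_CODE = 0

SEGMENT_NAMES = {
    SEG_LOW_RATIO_LOW_I: "low-ratio-low-I",
    SEG_LOW_RATIO_HIGH_I: "low-ratio-high-I",
    SEG_HIGH_RATIO_LOW_I: "high-ratio-low-I",
    SEG_HIGH_RATIO_HIGH_I: "high-ratio-high-I",
}


@dataclass(frozen=True)
class ColocPoints:
    """Retained scatter points with pixel provenance, plus exclusions."""

    x: np.ndarray  # normalized CN areas, >= 0
    y: np.ndarray  # normalized CC areas, >= 0
    rows: np.ndarray
    cols: np.ndarray
    excluded_rows: np.ndarray
    excluded_cols: np.ndarray

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def n_excluded(self) -> int:
        return self.excluded_rows.size


def coloc_points(
    cn_map: AreaMap, cc_map: AreaMap, cell_mask: np.ndarray
) -> ColocPoints:
    """Assemble the scatter from cell pixels; negatives are excluded.

    Every cell-mask pixel ends up either retained or excluded.
    """
    mask = validate_cell_mask(cell_mask)
    if cn_map.values.shape != mask.shape or cc_map.values.shape != mask.shape:
        raise ValueError("area map shape does not match the cell mask")
    rows, cols = np.nonzero(mask)
    x = cn_map.values[rows, cols]
    y = cc_map.values[rows, cols]
    keep = (x >= 0) & (y >= 0)
    if not keep.any():
        raise ValueError("no cell pixel has non-negative CN and CC values")
    return ColocPoints(
        x=x[keep],
        y=y[keep],
        rows=rows[keep],
        cols=cols[keep],
        excluded_rows=rows[~keep],
        excluded_cols=cols[~keep],
    )


def density_mode(points: ColocPoints, grid_size: int = 256) -> tuple[float, float]:
    """Mode of a Gaussian KDE (Scott bandwidth) over the retained points,
    located on a ``grid_size`` x ``grid_size`` evaluation grid."""
    if points.n_points < 10:
        raise ValueError(
            f"density mode needs at least 10 points, got {points.n_points}; "
            "use a larger image or phantom"
        )
    kde = gaussian_kde(np.vstack([points.x, points.y]))
    gx = np.linspace(points.x.min(), points.x.max(), grid_size)
    gy = np.linspace(points.y.min(), points.y.max(), grid_size)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    i, j = np.unravel_index(int(np.argmax(dens)), dens.shape)
    return float(gx[i]), float(gy[j])


@dataclass(frozen=True)
class ColocPartition:
    """Four-segment geometry: central slope and intensity boundary."""

    slope: float  # CC/CN ratio at the density mode
    t0: float  # intensity boundary (projection length on the central line)
    mode: tuple[float, float]
    t0_factor: float = 1.05

    def __post_init__(self):
        if self.slope <= 0 or self.t0 <= 0:
            raise ValueError("central slope and intensity boundary must be positive")

    def projection(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Length of the projection onto the central direction (1, slope)."""
        return (np.asarray(x) + self.slope * np.asarray(y)) / np.hypot(1.0, self.slope)


def fit_partition(
    points: ColocPoints, t0_factor: float = 1.05, grid_size: int = 256
) -> ColocPartition:
    """Build the partition geometry from the scatter's density mode.

    The central slope is the CC/CN ratio at the mode; the intensity
    boundary sits ``t0_factor`` (default 1.05, i.e. just beyond) times
    the mode's projection along the central line. Rebuilding the
    geometry after a common positive rescale of both maps relabels every
    point identically.
    """
    mx, my = density_mode(points, grid_size=grid_size)
    if mx <= 0 or my <= 0:
        raise ValueError(
            f"density mode ({mx:g}, {my:g}) touches an axis; the central "
            "slope through the origin is undefined"
        )
    slope = my / mx
    t_mode = (mx + slope * my) / np.hypot(1.0, slope)
    return ColocPartition(
        slope=slope, t0=t0_factor * t_mode, mode=(mx, my), t0_factor=t0_factor
    )


def partition(points: ColocPoints, geometry: ColocPartition) -> np.ndarray:
    """Segment label per retained point.

    Boundary tie-break: points exactly on the central line or on the
    intensity boundary go to the lower-ratio / lower-intensity segment.
    The four segments partition the retained points exactly.
    """
    above = points.y > geometry.slope * points.x  # high CC/CN ratio side
    high_i = geometry.projection(points.x, points.y) > geometry.t0
    labels = np.full(points.n_points, SEG_LOW_RATIO_LOW_I, dtype=np.int64)
    labels[~above & high_i] = SEG_LOW_RATIO_HIGH_I
    labels[above & ~high_i] = SEG_HIGH_RATIO_LOW_I
    labels[above & high_i] = SEG_HIGH_RATIO_HIGH_I
    return labels


def back_project(
    points: ColocPoints, labels: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Paint segment labels back onto the pixel grid.

    Output codes: 0 background (outside the mask), 1-4 segments,
    5 excluded pixels. Reading the image back at the point coordinates
    reproduces the label list exactly.
    """
    labels = np.asarray(labels)
    if labels.shape != points.x.shape:
        raise ValueError("labels do not align with the point list")
    if points.n_points and (points.rows.max() >= shape[0] or points.cols.max() >= shape[1]):
        raise ValueError(f"point coordinates exceed image shape {shape}")
    image = np.full(shape, BACKGROUND_CODE, dtype=np.int64)
    image[points.rows, points.cols] = labels
    image[points.excluded_rows, points.excluded_cols] = EXCLUDED_CODE
    return image
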