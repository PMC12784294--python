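"""End-to-end workflows.

Two orchestrations tie the stages together:

* single-tag localization — preprocess, segment, integrate the nitrile
  band, normalize to the nuclear DNA reference, and summarize the
  normalized abundance per compartment;
* two-tag colocalization — preprocess, segment, build normalized CN and
  CC maps, assemble the scatter, fit the density-based partition, and
  back-project the segment labels.

Both are deterministic given their inputs and record enough provenance
(config hash, seed) for bit-exact replay.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import (
    ColocPartition,
    ColocPoints,
    back_project,
    coloc_points,
    fit_partition,
    partition,
)
from .containers import HyperspectralCube
from .preprocess import PreprocessConfig, preprocess_cube
from .quantify import (
    ALKYNE_BAND_CENTER,
    AreaMap,
    BandWindow,
    DNA_BAND_CENTER,
    DRUG_BAND_CENTER,
    area_map,
    arsinh_transform,
    compartment_distributions,
    normalize_map,
    nuclear_reference,
)
from .segment import (
    FeatureStack,
    SegmentationModel,
    build_feature_stack,
    cell_mask,
    predict_classmap,
    train_classifier,
)

log = logging.getLogger(__name__)


def config_digest(*configs) -> str:
    """Short stable hash of a set of pydantic configs (for manifests)."""
    payload = json.dumps(
        [c.model_dump(mode="json") if hasattr(c, "model_dump") else c for c in configs],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def train_from_phantoms(
    cubes: list[HyperspectralCube],
    annotations: list[np.ndarray],
    seed: int = 0,
    preprocess_cfg: PreprocessConfig | None = None,
) -> SegmentationModel:
    """Preprocess training cubes, build feature stacks, fit the classifier."""
    stacks = []
    for cube in cubes:
        processed, _ = preprocess_cube(cube, preprocess_cfg)
        stacks.append(build_feature_stack(processed))
    return train_classifier(stacks, annotations, seed=seed)


@dataclass
class LocalizationResult:
    cube: HyperspectralCube  # preprocessed
    class_map: np.ndarray
    cell_mask: np.ndarray
    normalized_map: AreaMap
    reference_value: float
    distributions: dict[int, np.ndarray]
    summary: pd.DataFrame  # per-class stats of the normalized areas
    arsinh_summary: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def run_localization(
    cube: HyperspectralCube,
    model: SegmentationModel,
    preprocess_cfg: PreprocessConfig | None = None,
    drug_window: BandWindow | None = None,
    reference_window: BandWindow | None = None,
) -> LocalizationResult:
    """Single-tag workflow: where does the nitrile-tagged drug sit?

    preprocess -> feature stack -> class map -> cell mask -> drug band
    area map -> nuclear DNA normalization -> per-compartment summaries
    (raw and arsinh-compressed).
    """
    drug_window = drug_window or BandWindow(center=DRUG_BAND_CENTER)
    reference_window = reference_window or BandWindow(center=DNA_BAND_CENTER)
    processed, report = preprocess_cube(cube, preprocess_cfg)
    stack = build_feature_stack(processed)
    class_map = predict_classmap(model, stack)
    mask = cell_mask(class_map)

    drug_map = area_map(processed, drug_window)
    ref_map = area_map(processed, reference_window)
    reference = nuclear_reference(ref_map, class_map)
    normalized = normalize_map(drug_map, reference)

    distributions, summary = compartment_distributions(normalized, class_map, mask)
    arsinh_map = AreaMap(
        values=arsinh_transform(normalized.values),
        window=normalized.window,
        normalized=True,
        reference_value=reference,
    )
    _, arsinh_summary = compartment_distributions(arsinh_map, class_map, mask)
    return LocalizationResult(
        cube=processed,
        class_map=class_map,
        cell_mask=mask,
        normalized_map=normalized,
        reference_value=reference,
        distributions=distributions,
        summary=summary,
        arsinh_summary=arsinh_summary,
        provenance={
            "n_spike_flags": report.n_spike_flags,
            "calibration_shift": report.calibration_shift,
        },
    )


@dataclass
class ColocResult:
    cube: HyperspectralCube
    class_map: np.ndarray
    cell_mask: np.ndarray
    cn_map: AreaMap
    cc_map: AreaMap
    points: ColocPoints
    geometry: ColocPartition
    labels: np.ndarray
    label_image: np.ndarray
    scatter: pd.DataFrame  # row, col, x, y, segment
    provenance: dict = field(default_factory=dict)


def run_coloc(
    cube: HyperspectralCube,
    model: SegmentationModel,
    preprocess_cfg: PreprocessConfig | None = None,
    cn_window: BandWindow | None = None,
    cc_window: BandWindow | None = None,
    reference_window: BandWindow | None = None,
    t0_factor: float = 1.05,
) -> ColocResult:
    """Two-tag workflow: nitrile drug (x) vs alkyne lipid (y) per pixel."""
    cn_window = cn_window or BandWindow(center=DRUG_BAND_CENTER)
    cc_window = cc_window or BandWindow(center=ALKYNE_BAND_CENTER)
    reference_window = reference_window or BandWindow(center=DNA_BAND_CENTER)

    processed, report = preprocess_cube(cube, preprocess_cfg)
    stack = build_feature_stack(processed)
    class_map = predict_classmap(model, stack)
    mask = cell_mask(class_map)

    reference = nuclear_reference(area_map(processed, reference_window), class_map)
    cn = normalize_map(area_map(processed, cn_window), reference)
    cc = normalize_map(area_map(processed, cc_window), reference)

    points = coloc_points(cn, cc, mask)
    geometry = fit_partition(points, t0_factor=t0_factor)
    labels = partition(points, geometry)
    label_image = back_project(points, labels, mask.shape)
    scatter = pd.DataFrame(
        {
            "row": points.rows,
            "col": points.cols,
            "x": points.x,
            "y": points.y,
            "segment": labels,
        }
    )
    return ColocResult(
        cube=processed,
        class_map=class_map,
        cell_mask=mask,
        cn_map=cn,
        cc_map=cc,
        points=points,
        geometry=geometry,
        labels=labels,
        label_image=label_image,
        scatter=scatter,
        provenance={
            "n_spike_flags": report.n_spike_flags,
            "calibration_shift": report.calibration_shift,
            "central_slope": geometry.slope,
            "t0": geometry.t0,
        },
    )
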