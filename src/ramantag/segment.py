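"""Supervised compartment segmentation and the cell/background mask.

Each pixel is classified independently from eight band-area features
(789, 1342, 1267, 1100, 1447, 1661, 2850, 2940 cm^-1, all +-15) chosen
to avoid the drug's own bands, so the segmentation does not change with
drug loading. A random forest is trained on partially annotated images
(0 = unlabeled) and predicts the four compartment labels per pixel.

The cell mask derives from a predicted class map by thresholding at
label >= 2, one erosion and one dilation with a 3x3 square, keeping the
largest 8-connected component, and filling interior holes.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .containers import HyperspectralCube, validate_class_map
from .errors import AxisError
from .quantify import BandWindow, band_area

#: The eight feature windows, in canonical order.
FEATURE_CENTERS = (789.0, 1342.0, 1267.0, 1100.0, 1447.0, 1661.0, 2850.0, 2940.0)
FEATURE_HALF_WIDTH = 15.0


def feature_windows() -> list[BandWindow]:
    return [BandWindow(center=c, half_width=FEATURE_HALF_WIDTH) for c in FEATURE_CENTERS]


@dataclass(frozen=True)
class FeatureStack:
    """(H, W, 8) band-area features plus the window list that produced them."""

    values: np.ndarray
    windows: tuple[tuple[float, float], ...]  # (center, half_width) per feature

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[-1] != len(self.windows):
            raise ValueError("feature stack shape does not match its window list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature stack contains non-finite values")


def build_feature_stack(cube: HyperspectralCube) -> FeatureStack:
    """Compute the eight band-area maps, in the canonical window order."""
    windows = feature_windows()
    maps = []
    for window in windows:
        try:
            maps.append(band_area(cube.intensities, cube.wavenumbers, window))
        except AxisError as exc:
            raise AxisError(f"feature window {window.center:g} cm^-1: {exc}")
    return FeatureStack(
        values=np.stack(maps, axis=-1),
        windows=tuple((w.center, w.half_width) for w in windows),
    )


@dataclass
class SegmentationModel:
    """A trained per-pixel classifier bound to its feature window list."""

    forest: RandomForestClassifier
    windows: tuple[tuple[float, float], ...]
    seed: int
    training_accuracy: float

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold a SegmentationModel")
        return model


def train_classifier(
    stacks: list[FeatureStack],
    annotations: list[np.ndarray],
    seed: int = 0,
    n_estimators: int = 100,
) -> SegmentationModel:
    """Fit a random forest on the labeled pixels of partially annotated images.

    Annotations use 0 for unlabeled pixels and the compartment codes 1-4
    elsewhere. At least two distinct classes and four labeled pixels per
    class (on average) are required. Deterministic under ``seed``.
    """
    if len(stacks) != len(annotations):
        raise ValueError("need one annotation image per feature stack")
    features, labels = [], []
    window_set = stacks[0].windows
    for stack, ann in zip(stacks, annotations):
        if stack.windows != window_set:
            raise ValueError("all training stacks must share one window list")
        ann = validate_class_map(ann, allow_unlabeled=True)
        if ann.shape != stack.values.shape[:2]:
            raise ValueError("annotation shape does not match its feature stack")
        sel = ann > 0
        features.append(stack.values[sel])
        labels.append(ann[sel])
    X = np.concatenate(features, axis=0)
    y = np.concatenate(labels, axis=0)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("annotations must contain at least 2 distinct classes")
    if y.size < 4 * classes.size:
        raise ValueError(
            f"too few labeled pixels ({y.size}) for {classes.size} classes"
        )
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        criterion="entropy",
        max_depth=None,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    accuracy = float(forest.score(X, y))
    return SegmentationModel(
        forest=forest, windows=window_set, seed=seed, training_accuracy=accuracy
    )


def predict_classmap(model: SegmentationModel, stack: FeatureStack) -> np.ndarray:
    """Per-pixel compartment labels in {1..4}."""
    if stack.windows != model.windows:
        raise ValueError(
            "feature stack windows do not match the windows the model was trained on"
        )
    h, w, k = stack.values.shape
    labels = model.forest.predict(stack.values.reshape(-1, k))
    return labels.reshape(h, w).astype(np.int64)


_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


def cell_mask(class_map: np.ndarray) -> np.ndarray:
    """Binary cell area from a class map.

    label >= 2 (threshold 1.5) -> one 3x3 erosion -> one 3x3 dilation ->
    keep the largest 8-connected component -> fill holes. An empty mask
    is a legal result.
    """
    labels = validate_class_map(class_map)
    mask = labels >= 2
    mask = ndimage.binary_erosion(mask, structure=_STRUCT_3X3)
    mask = ndimage.binary_dilation(mask, structure=_STRUCT_3X3)
    if not mask.any():
        return mask
    components, n = ndimage.label(mask, structure=_STRUCT_3X3)
    if n > 1:
        sizes = ndimage.sum_labels(mask, components, index=np.arange(1, n + 1))
        mask = components == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


def apply_mask_override(mask: np.ndarray, override: np.ndarray | None) -> np.ndarray:
    """Apply a manual repair mask (replaces the automatic mask where given).

    The override image uses 0 = keep automatic value, 1 = force outside,
    2 = force inside; holes are re-filled afterwards.
    """
    if override is None:
        return mask
    override = np.asarray(override)
    if override.shape != mask.shape:
        raise ValueError("override shape does not match mask")
    out = mask.copy()
    out[override == 1] = False
    out[override == 2] = True
    return ndimage.binary_fill_holes(out)
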