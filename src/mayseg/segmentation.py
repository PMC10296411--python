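"""Mayfly-optimized Kapur segmentation and mask-overlap metrics.

``segment`` runs the whole localization stage: build the gray-level
histogram, maximize the Kapur objective over threshold vectors with the
mayfly swarm, turn the thresholds into a label map, and extract a binary
tumor mask.  The tumor-candidate class is the one whose mean intensity is
farthest from the global foreground mean (tumors are hyper- or
hypo-intense relative to tissue); the mask is its largest 8-connected
component.

Overlap metrics: Tanimoto coefficient (= Jaccard index) ``|A∩B| / |A∪B|``
and Dice overlap ``2|A∩B| / (|A|+|B|)``; always ``tanimoto <= dice``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .kapur import (
    DEFAULT_LEVELS,
    Histogram,
    KapurTable,
    ThresholdVector,
    compute_histogram,
    kapur_objective,
)
from .mayfly import MFOConfig, optimize

__all__ = [
    "SegmentationResult",
    "SegmentationMetrics",
    "decode_thresholds",
    "optimize_thresholds",
    "segment",
    "tanimoto",
    "dice_overlap",
    "mask_area",
    "evaluate_masks",
]


@dataclass(frozen=True)
class SegmentationResult:
    thresholds: ThresholdVector | None
    label_map: np.ndarray  # int class index per pixel
    tumor_mask: np.ndarray  # uint8 0/1
    objective_value: float
    tumor_class: int | None
    degenerate: bool = False  # single-gray-level input; empty mask


@dataclass(frozen=True)
class SegmentationMetrics:
    tc: float
    doi: float
    area: float
    n_pixels: int


def decode_thresholds(x: np.ndarray, levels: int = DEFAULT_LEVELS) -> tuple[int, ...]:
    """Map a real MFO position to a valid strictly increasing integer
    threshold vector: sort, round, clamp to [1, L-1], resolve duplicates."""
    t = np.sort(np.round(np.asarray(x, dtype=float))).astype(int)
    t = np.clip(t, 1, levels - 1)
    for i in range(1, len(t)):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1
    t = np.clip(t, 1, levels - 1)
    for i in range(len(t) - 2, -1, -1):  # clipping at the top can re-collide
        if t[i] >= t[i + 1]:
            t[i] = t[i + 1] - 1
    return tuple(int(v) for v in t)


def optimize_thresholds(
    hist: Histogram,
    n_classes: int,
    mfo_config: MFOConfig | None = None,
    seed: int = 0,
    empty_class_penalty: float = 0.0,
) -> tuple[ThresholdVector, float, np.ndarray]:
    """Maximize the Kapur objective with the mayfly swarm.

    ``empty_class_penalty`` is subtracted per zero-mass class during the
    search: Kapur's raw criterion can prefer thresholds that leave a class
    empty (merging spiky modes gains entropy), which is useless for
    segmentation, so ``segment`` searches with a penalty large enough to
    exclude such splits.  Returns the decoded threshold vector, its
    (unpenalized) objective value, and the MFO best-value trace.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    L = hist.levels
    if mfo_config is None:
        mfo_config = MFOConfig(bounds=tuple((1.0, float(L - 1)) for _ in range(n_classes - 1)), seed=seed)
    if len(mfo_config.bounds) != n_classes - 1:
        raise ValueError("mfo_config dimensionality must be n_classes - 1")
    table = KapurTable(hist)
    if empty_class_penalty:
        objective = lambda x: (
            table.value(t := decode_thresholds(x, L))
            - empty_class_penalty * table.n_empty_classes(t)
        )
    else:
        objective = lambda x: table.value(decode_thresholds(x, L))
    best_x, _, trace = optimize(mfo_config, objective)
    T = ThresholdVector(decode_thresholds(best_x, L), levels=L)
    return T, table.value(T.thresholds), trace


def segment(
    image: np.ndarray,
    n_classes: int = 4,
    mfo_config: MFOConfig | None = None,
    seed: int = 0,
) -> SegmentationResult:
    """Full localization stage on an 8-bit grayscale image."""
    image = np.asarray(image)
    if image.min() == image.max():  # degenerate: nothing to threshold
        return SegmentationResult(
            thresholds=None,
            label_map=np.zeros(image.shape, dtype=int),
            tumor_mask=np.zeros(image.shape, dtype=np.uint8),
            objective_value=0.0,
            tumor_class=None,
            degenerate=True,
        )
    hist = compute_histogram(image)
    # penalty > n_classes * ln(L): no entropy gain can offset an empty class
    penalty = (n_classes + 1) * float(np.log(hist.levels))
    T, value, _ = optimize_thresholds(
        hist, n_classes, mfo_config, seed=seed, empty_class_penalty=penalty
    )
    # half-open classes: level t belongs to the upper class
    label_map = np.digitize(image, bins=np.asarray(T.thresholds), right=False)

    # tumor candidate: non-background class farthest from the foreground mean
    foreground = label_map > 0
    if not foreground.any():
        tumor_mask = np.zeros(image.shape, dtype=np.uint8)
        return SegmentationResult(T, label_map, tumor_mask, value, None, degenerate=True)
    fg_mean = float(image[foreground].mean())
    best_cls, best_dist = None, -1.0
    for cls in range(1, n_classes):
        sel = label_map == cls
        if not sel.any():
            continue
        dist = abs(float(image[sel].mean()) - fg_mean)
        if dist > best_dist:
            best_cls, best_dist = cls, dist
    mask = label_map == best_cls
    labeled = measure.label(mask, connectivity=2)  # 8-connectivity
    if labeled.max() > 0:
        largest = int(np.argmax(np.bincount(labeled.ravel())[1:])) + 1
        tumor_mask = (labeled == largest).astype(np.uint8)
    else:
        tumor_mask = np.zeros(image.shape, dtype=np.uint8)
    return SegmentationResult(T, label_map, tumor_mask, value, best_cls)


def _check_pair(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def tanimoto(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B|; 1.0 when both masks are empty."""
    a, b = _check_pair(mask_a, mask_b)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def dice_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap index 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a, b = _check_pair(mask_a, mask_b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2 * int(np.logical_and(a, b).sum()) / denom


def mask_area(mask: np.ndarray, pixel_area: float = 1.0) -> tuple[float, int]:
    """Physical area and pixel count of a binary mask."""
    n_pixels = int(np.asarray(mask).astype(bool).sum())
    return n_pixels * pixel_area, n_pixels


def evaluate_masks(
    predicted: np.ndarray, truth: np.ndarray, pixel_area: float = 1.0
) -> SegmentationMetrics:
    """Overlap metrics of a predicted mask against ground truth."""
    area, n_pixels = mask_area(predicted, pixel_area)
    return SegmentationMetrics(
        tc=tanimoto(predicted, truth),
        doi=dice_overlap(predicted, truth),
        area=area,
        n_pixels=n_pixels,
    )
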