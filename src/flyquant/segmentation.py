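"""Probability-mask segmentation: thresholding, labeling and size filtering.

The pipeline mirrors the automated quantification workflow: binarize a
per-pixel probability map at a probability threshold, label connected
components, and drop objects below a minimum pixel size.  An
intensity-threshold variant provides the "standard method" reference arm for
method-agreement validation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import IntensityImage, ProbabilityMask

__all__ = [
    "SegmentationParams",
    "LabeledObjectMap",
    "binarize_probability",
    "label_objects",
    "filter_min_size",
    "segment",
    "intensity_segment_reference",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds controlling object detection.

    ``probability_mode="pixel"`` thresholds individual pixels;
    ``"object_mean"`` binarizes at half the threshold and then drops objects
    whose mean probability does not exceed the threshold.
    """

    probability_threshold: float
    min_size_px: int
    connectivity: Literal[4, 8] = 8
    probability_mode: Literal["pixel", "object_mean"] = "pixel"

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability_threshold must be in [0, 1]")
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.probability_mode not in ("pixel", "object_mean"):
            raise ValueError("probability_mode must be 'pixel' or 'object_mean'")

    def fingerprint(self) -> str:
        return (
            f"thr={self.probability_threshold:g};min={self.min_size_px};"
            f"conn={self.connectivity};mode={self.probability_mode}"
        )


@dataclass
class LabeledObjectMap:
    """Integer-labeled connected objects plus a per-object summary table.

    ``labels`` uses 0 for background and consecutive integers 1..K for
    objects, ordered by the raster position of each object's first pixel.
    ``objects`` has columns ``label, area_px, centroid_row, centroid_col,
    mean_probability``.
    """

    labels: np.ndarray
    objects: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        k = int(self.labels.max(initial=0))
        got = self.objects["label"].tolist()
        if got != list(range(1, k + 1)):
            raise ValueError("object labels must be consecutive 1..K")
        counts = np.bincount(self.labels.ravel(), minlength=k + 1)
        if not np.array_equal(counts[1:], self.objects["area_px"].to_numpy()):
            raise ValueError("objects table inconsistent with label grid")

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def total_area_px(self) -> int:
        return int(self.objects["area_px"].sum())

    def binary(self) -> np.ndarray:
        return self.labels > 0


def binarize_probability(mask: ProbabilityMask | np.ndarray, thr: float) -> np.ndarray:
    """Binary grid with True where probability strictly exceeds ``thr``."""
    if not 0.0 <= thr <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    probs = mask.probs if isinstance(mask, ProbabilityMask) else np.asarray(mask)
    return probs > thr


def _build_map(
    labels: np.ndarray, n: int, values: np.ndarray | None
) -> LabeledObjectMap:
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    if n:
        idx = np.arange(1, n + 1)
        crow = ndimage.mean(
            np.indices(labels.shape)[0].astype(float), labels, idx
        )
        ccol = ndimage.mean(
            np.indices(labels.shape)[1].astype(float), labels, idx
        )
        meanp = (
            ndimage.mean(values, labels, idx)
            if values is not None
            else np.full(n, np.nan)
        )
    else:
        crow = ccol = meanp = np.array([], dtype=float)
    objects = pd.DataFrame(
        {
            "label": np.arange(1, n + 1, dtype=int),
            "area_px": areas.astype(int),
            "centroid_row": np.atleast_1d(crow).astype(float),
            "centroid_col": np.atleast_1d(ccol).astype(float),
            "mean_probability": np.atleast_1d(meanp).astype(float),
        }
    )
    return LabeledObjectMap(labels=labels.astype(np.int32), objects=objects)


def label_objects(
    binary: np.ndarray,
    connectivity: Literal[4, 8] = 8,
    values: np.ndarray | None = None,
) -> LabeledObjectMap:
    """Label maximal connected components of a boolean grid.

    Labels are assigned in raster order of each component's first pixel, so
    the output is deterministic.  ``values`` (optional, same shape) feeds the
    per-object ``mean_probability`` column.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2 or binary.size == 0:
        raise ValueError("binary grid must be non-empty 2D")
    labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    return _build_map(labels, n, values)


def filter_min_size(objmap: LabeledObjectMap, min_size_px: int) -> LabeledObjectMap:
    """Drop objects smaller than ``min_size_px``; survivors keep their order.

    An object of exactly ``min_size_px`` pixels is retained.
    """
    if min_size_px < 1:
        raise ValueError("min_size_px must be >= 1")
    keep = objmap.objects["area_px"].to_numpy() >= min_size_px
    return _relabel(objmap, keep)


def _relabel(objmap: LabeledObjectMap, keep: np.ndarray) -> LabeledObjectMap:
    old = objmap.objects["label"].to_numpy()[keep]
    lut = np.zeros(int(objmap.labels.max(initial=0)) + 1, dtype=np.int32)
    lut[old] = np.arange(1, len(old) + 1, dtype=np.int32)
    objects = objmap.objects.loc[keep].reset_index(drop=True).copy()
    objects["label"] = np.arange(1, len(old) + 1, dtype=int)
    return LabeledObjectMap(labels=lut[objmap.labels], objects=objects)


def segment(mask: ProbabilityMask, params: SegmentationParams) -> LabeledObjectMap:
    """Full segmentation of a probability mask.

    Pixel mode: ``binarize_probability`` -> ``label_objects`` ->
    ``filter_min_size``.  Object-mean mode: binarize at half the threshold,
    label, drop objects whose mean probability <= threshold, then size-filter.
    """
    thr = params.probability_threshold
    if params.probability_mode == "pixel":
        objmap = label_objects(
            binarize_probability(mask, thr), params.connectivity, values=mask.probs
        )
    else:
        objmap = label_objects(
            binarize_probability(mask, 0.5 * thr),
            params.connectivity,
            values=mask.probs,
        )
        objmap = _relabel(
            objmap, objmap.objects["mean_probability"].to_numpy() > thr
        )
    return filter_min_size(objmap, params.min_size_px)


def intensity_segment_reference(
    image: IntensityImage,
    intensity_threshold: float,
    min_size_px: int,
    connectivity: Literal[4, 8] = 8,
) -> LabeledObjectMap:
    """Reference segmentation by raw-intensity thresholding.

    Same label/size-filter pipeline as :func:`segment` but binarizing
    ``intensity > intensity_threshold``; used as the standard-method arm when
    validating probability-based segmentation.
    """
    objmap = label_objects(
        image.pixels > intensity_threshold, connectivity, values=image.pixels
    )
    return filter_min_size(objmap, min_size_px)
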