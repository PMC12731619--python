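"""ROI-normalized area, colocalization, CTCF and method-agreement metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .io import IntensityImage
from .segmentation import LabeledObjectMap

__all__ = [
    "SignalQuant",
    "ColocQuant",
    "CtcfResult",
    "MethodAgreement",
    "area_fraction",
    "colocalize",
    "ctcf",
    "method_agreement",
]


@dataclass(frozen=True)
class SignalQuant:
    """Signal area inside the ROI, as pixels and as a percentage of the ROI."""

    roi_area_px: int
    signal_area_px: int
    area_percent: float


@dataclass(frozen=True)
class ColocQuant:
    """Overlap of two binarized signals within the ROI.

    ``partial`` counts an object of channel A as colocalized if it shares at
    least one ROI pixel with channel B; ``total`` requires every ROI pixel of
    the object to lie within B.  Objects with no pixels in the ROI are not
    counted.
    """

    overlap_area_px: int
    overlap_percent_of_roi: float
    mode: Literal["partial", "total"]
    n_A_objects_colocalized: int
    n_A_objects_total: int


@dataclass(frozen=True)
class CtcfResult:
    """Corrected total cell fluorescence: ``ID - area * background_mean``."""

    integrated_density: float
    cell_area_px: int
    background_mean: float
    ctcf: float


@dataclass(frozen=True)
class MethodAgreement:
    """Object-count agreement between a reference and an automated map."""

    n_objects_reference: int
    n_objects_automated: int
    n_matched: int
    n_only_reference: int
    n_only_automated: int


def _check_roi(roi: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != shape:
        raise ValueError(f"ROI shape {roi.shape} != map shape {shape}")
    if not roi.any():
        raise ValueError("ROI is empty")
    return roi


def area_fraction(objmap: LabeledObjectMap, roi: np.ndarray) -> SignalQuant:
    """Labeled signal area inside the ROI as a percentage of the ROI area."""
    roi = _check_roi(roi, objmap.labels.shape)
    roi_area = int(roi.sum())
    signal_area = int((objmap.binary() & roi).sum())
    return SignalQuant(
        roi_area_px=roi_area,
        signal_area_px=signal_area,
        area_percent=100.0 * signal_area / roi_area,
    )


def colocalize(
    objA: LabeledObjectMap,
    objB: LabeledObjectMap,
    roi: np.ndarray,
    mode: Literal["partial", "total"] = "partial",
) -> ColocQuant:
    """Area overlap of two labeled maps within the ROI, plus per-object counts."""
    if mode not in ("partial", "total"):
        raise ValueError("mode must be 'partial' or 'total'")
    if objA.labels.shape != objB.labels.shape:
        raise ValueError("label maps must share a shape")
    roi = _check_roi(roi, objA.labels.shape)
    roi_area = int(roi.sum())
    in_b = objB.binary() & roi
    overlap = int((objA.binary() & in_b).sum())

    labels_roi = np.where(roi, objA.labels, 0)
    n_total = 0
    n_coloc = 0
    for lab in range(1, objA.n_objects + 1):
        obj_pixels = labels_roi == lab
        n_px = int(obj_pixels.sum())
        if n_px == 0:
            continue  # object entirely outside the ROI: not evaluable
        n_total += 1
        n_in_b = int((obj_pixels & in_b).sum())
        if mode == "partial":
            n_coloc += n_in_b >= 1
        else:
            n_coloc += n_in_b == n_px
    return ColocQuant(
        overlap_area_px=overlap,
        overlap_percent_of_roi=100.0 * overlap / roi_area,
        mode=mode,
        n_A_objects_colocalized=n_coloc,
        n_A_objects_total=n_total,
    )


def ctcf(
    image: IntensityImage, cell_mask: np.ndarray, background_mask: np.ndarray
) -> CtcfResult:
    """Corrected total cell fluorescence of ``cell_mask`` against a background.

    ``ctcf = sum(I[cell]) - |cell| * mean(I[background])``; the two masks must
    be non-empty and disjoint.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if cell.shape != image.shape or bg.shape != image.shape:
        raise ValueError("mask shapes must match the image")
    if not cell.any() or not bg.any():
        raise ValueError("cell and background masks must be non-empty")
    if (cell & bg).any():
        raise ValueError("cell and background masks overlap")
    integrated = float(image.pixels[cell].sum())
    area = int(cell.sum())
    bg_mean = float(image.pixels[bg].mean())
    return CtcfResult(
        integrated_density=integrated,
        cell_area_px=area,
        background_mean=bg_mean,
        ctcf=integrated - area * bg_mean,
    )


def method_agreement(
    reference: LabeledObjectMap, automated: LabeledObjectMap, roi: np.ndarray
) -> MethodAgreement:
    """Pair reference and automated objects by pixel overlap inside the ROI.

    Matching is maximum-cardinality bipartite matching over the any-overlap
    graph (Hopcroft-Karp), which is deterministic for a fixed input.  Objects
    without ROI pixels are ignored on both sides.
    """
    if reference.labels.shape != automated.labels.shape:
        raise ValueError("label maps must share a shape")
    roi = _check_roi(roi, reference.labels.shape)
    ref = np.where(roi, reference.labels, 0)
    aut = np.where(roi, automated.labels, 0)
    ref_ids = np.unique(ref[ref > 0])
    aut_ids = np.unique(aut[aut > 0])
    n_ref, n_aut = len(ref_ids), len(aut_ids)
    if n_ref == 0 or n_aut == 0:
        return MethodAgreement(n_ref, n_aut, 0, n_ref, n_aut)
    ref_idx = np.searchsorted(ref_ids, ref[(ref > 0) & (aut > 0)])
    aut_idx = np.searchsorted(aut_ids, aut[(ref > 0) & (aut > 0)])
    graph = csr_matrix(
        (np.ones(len(ref_idx)), (ref_idx, aut_idx)), shape=(n_ref, n_aut)
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    n_matched = int((match >= 0).sum())
    return MethodAgreement(
        n_objects_reference=n_ref,
        n_objects_automated=n_aut,
        n_matched=n_matched,
        n_only_reference=n_ref - n_matched,
        n_only_automated=n_aut - n_matched,
    )
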