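"""Myelin mask production and curation into measurable sheaths.

Two mask sources are supported: the built-in reference segmenter (automatic
global threshold on the dark, osmium-stained myelin) and externally produced
masks such as DCNN output, ingested from disk. Either way the mask is curated
into a label map of ring-shaped components: a sheath is measurable only if its
myelin component encloses exactly one background hole (the axon lumen) and does
not touch the image border.

Connectivity: foreground components are 8-connected, holes 4-connected — the
standard complementary pairing that avoids topological paradoxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import filters, morphology

from .exceptions import MaskError, SegmentationError

REASON_BORDER = "touches border"
REASON_NO_HOLE = "no hole"
REASON_MULTI_HOLE = "multiple holes"

_HOLE_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class MyelinMask:
    """Binary myelin raster plus provenance (reference-segmenter | external)."""

    data: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise MaskError(f"mask must be 2-D, got ndim={self.data.ndim}")
        if self.data.dtype != bool:
            object.__setattr__(self, "data", self.data.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SheathLabelMap:
    """Integer-labeled raster of accepted sheaths plus per-component records.

    ``labels`` is 0 for background and ``k >= 1`` for accepted sheath ``k``.
    ``records`` has one row per connected component of the input mask (accepted
    or not) with pixel count, hole count, border flag, bounding box, and the
    rejection reason where applicable.
    """

    labels: np.ndarray
    records: pd.DataFrame

    @property
    def accepted_ids(self) -> list[int]:
        return [int(i) for i in self.records.loc[self.records.accepted, "sheath_id"]]

    def rejection_log(self) -> pd.DataFrame:
        rej = self.records.loc[~self.records.accepted, ["component", "reject_reason", "pixel_count"]]
        return rej.rename(columns={"component": "label", "reject_reason": "reason"}).reset_index(drop=True)


def segment_myelin_reference(
    image: np.ndarray,
    threshold_mode: str = "otsu",
    min_object_px: int = 64,
    fixed_threshold: float | None = None,
    min_separation: float = 2.5,
) -> MyelinMask:
    """Segment myelin as the dark phase of a single-channel image.

    Pixels at or below the threshold (Otsu by default, or a fixed value with
    ``threshold_mode='fixed'``) are myelin candidates; connected
    candidates smaller than ``min_object_px`` are removed.

    In Otsu mode the split must separate two real intensity populations: the
    class means must differ by at least ``min_separation`` times the pooled
    within-class standard deviation, otherwise the image has no bimodal
    intensity structure (constant, or background noise only) and a
    :class:`SegmentationError` is raised. A fixed threshold skips the check.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise SegmentationError(f"expected a single-channel 2-D image, got shape {img.shape}")
    if img.min() == img.max():
        raise SegmentationError("no bimodal intensity structure: image is constant")
    if threshold_mode == "otsu":
        thr = filters.threshold_otsu(img)
        lower = img[img <= thr].astype(float)
        upper = img[img > thr].astype(float)
        pooled_sd = np.sqrt(lower.var() + upper.var())
        separation = (upper.mean() - lower.mean()) / max(pooled_sd, np.finfo(float).eps)
        if separation < min_separation:
            raise SegmentationError(
                "no bimodal intensity structure: Otsu class separation "
                f"{separation:.2f} below {min_separation}"
            )
    elif threshold_mode == "fixed":
        if fixed_threshold is None:
            raise SegmentationError("threshold_mode='fixed' requires fixed_threshold")
        thr = fixed_threshold
    else:
        raise SegmentationError(f"unknown threshold_mode {threshold_mode!r}")
    candidates = img <= thr
    # objects strictly smaller than min_object_px are removed
    cleaned = morphology.remove_small_objects(candidates, max_size=int(min_object_px) - 1, connectivity=2)
    return MyelinMask(data=cleaned, provenance="reference-segmenter")


def load_external_mask(path: str | Path, image_shape: tuple[int, int]) -> MyelinMask:
    """Load an externally produced (e.g. DCNN) myelin mask and validate it.

    The raster must be binary, or binarizable at 50% of its maximum value
    (e.g. {0, 255} or {0, 65535}); more than two distinct values is an error.
    """
    raster = tifffile.imread(str(path))
    raster = np.asarray(raster)
    if raster.shape != tuple(image_shape):
        raise MaskError(f"mask shape {raster.shape} does not match image shape {tuple(image_shape)}")
    uniq = np.unique(raster)
    if uniq.size > 2:
        raise MaskError(f"mask is not binary: found {uniq.size} distinct values")
    data = raster > (raster.max() / 2.0) if raster.max() > 0 else np.zeros_like(raster, dtype=bool)
    return MyelinMask(data=data, provenance="external")


def _component_holes(component: np.ndarray) -> int:
    """Count background holes (4-connected) fully enclosed by the component."""
    padded = np.pad(component, 1)
    filled = ndimage.binary_fill_holes(padded, structure=_HOLE_STRUCTURE)
    holes = filled & ~padded
    _, n = ndimage.label(holes, structure=_HOLE_STRUCTURE)
    return int(n)


def label_sheaths(mask: MyelinMask | np.ndarray) -> SheathLabelMap:
    """Curate a binary myelin mask into accepted ring-shaped sheath labels.

    Components are 8-connected. A component is rejected — excluded from
    measurement, with the reason logged — when it touches the image border or
    when it encloses a number of holes different from one.
    """
    data = mask.data if isinstance(mask, MyelinMask) else np.asarray(mask).astype(bool)
    comp_labels, n_comp = ndimage.label(data, structure=ndimage.generate_binary_structure(2, 2))
    rows, cols = data.shape
    out = np.zeros_like(comp_labels)
    records = []
    next_id = 1
    slices = ndimage.find_objects(comp_labels)
    for comp_idx, sl in enumerate(slices, start=1):
        component = comp_labels[sl] == comp_idx
        touches = (
            sl[0].start == 0 or sl[1].start == 0 or sl[0].stop == rows or sl[1].stop == cols
        )
        n_holes = _component_holes(component)
        reason = None
        if touches:
            reason = REASON_BORDER
        elif n_holes == 0:
            reason = REASON_NO_HOLE
        elif n_holes > 1:
            reason = REASON_MULTI_HOLE
        accepted = reason is None
        sheath_id = next_id if accepted else 0
        if accepted:
            out[sl][component] = next_id
            next_id += 1
        records.append(
            {
                "component": comp_idx,
                "sheath_id": sheath_id,
                "accepted": accepted,
                "reject_reason": reason,
                "pixel_count": int(component.sum()),
                "hole_count": n_holes,
                "touches_border": bool(touches),
                "bbox": (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            }
        )
    columns = [
        "component",
        "sheath_id",
        "accepted",
        "reject_reason",
        "pixel_count",
        "hole_count",
        "touches_border",
        "bbox",
    ]
    return SheathLabelMap(labels=out, records=pd.DataFrame(records, columns=columns))
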