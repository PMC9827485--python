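"""Rule-based macrophage detection and grading on rendered iron-stained
images.

This is a deliberately simple, fully deterministic stand-in for a trained
object detector: pixels are classified by HSV windows (blue hemosiderin
pigment, red nuclear counterstain, pale cytoplasm, near-white background),
cells are connected components of non-background pixels, components without
a nucleus are rejected as non-macrophages, and each detection is graded by
its blue-pigment pixel fraction using the same canonical content thresholds
as the slide generator.  Its output is an ordinary annotation set under the
reserved rater id ``"algorithm"``, so it feeds matching, agreement and
diagnostics exactly like a human rater.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, disk
from skimage.segmentation import watershed

from .scoring import (
    CANONICAL_THRESHOLDS,
    CellAnnotation,
    ThsRecord,
    compute_ths,
    grade_from_content,
)

BACKGROUND, CYTOPLASM, NUCLEUS, PIGMENT = 0, 1, 2, 3
_CLASS_NAMES = ("background", "cytoplasm", "nucleus", "pigment")


@dataclass(frozen=True)
class ColorParams:
    """HSV windows for pixel classification (hue in [0, 1]).

    The pigment hue window is widened for the slightly cyan-shifted
    Turnbull's blue reaction product; the nucleus window brackets the
    Nuclear-Fast-Red pink around the hue wrap-point.
    """

    pigment_hue: tuple[float, float] = (0.45, 0.80)
    pigment_hue_turnbull: tuple[float, float] = (0.42, 0.78)
    pigment_min_sat: float = 0.25
    nucleus_hue_max: float = 0.12       # or above nucleus_hue_wrap
    nucleus_hue_wrap: float = 0.88
    nucleus_min_sat: float = 0.25
    background_min_val: float = 0.93
    background_max_sat: float = 0.12

    def pigment_window(self, stain: str) -> tuple[float, float]:
        if stain == "turnbull_blue":
            return self.pigment_hue_turnbull
        return self.pigment_hue


@dataclass(frozen=True)
class PixelClassMap:
    """Dense per-pixel class labels for one image."""

    labels: np.ndarray = field(repr=False)  # uint8, one of the 4 classes

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_count(self, cls: int) -> int:
        return int(np.count_nonzero(self.labels == cls))


@dataclass(frozen=True)
class DetectedCell:
    """One detected macrophage with its pigment-derived grade."""

    x: float
    y: float
    cell_area: int
    pigment_fraction: float
    grade: int


def classify_pixels(
    image: np.ndarray,
    stain: str = "prussian_blue",
    params: ColorParams = ColorParams(),
) -> PixelClassMap:
    """Classify every pixel as pigment, nucleus, cytoplasm or background."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("an 8-bit RGB image (H, W, 3) is required")
    hsv = rgb2hsv(image)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]

    lo, hi = params.pigment_window(stain)
    pigment = (h >= lo) & (h <= hi) & (s >= params.pigment_min_sat)
    nucleus = (
        ((h <= params.nucleus_hue_max) | (h >= params.nucleus_hue_wrap))
        & (s >= params.nucleus_min_sat)
        & ~pigment
    )
    background = (
        (v >= params.background_min_val)
        & (s <= params.background_max_sat)
        & ~pigment
        & ~nucleus
    )
    labels = np.full(image.shape[:2], CYTOPLASM, dtype=np.uint8)
    labels[background] = BACKGROUND
    labels[nucleus] = NUCLEUS
    labels[pigment] = PIGMENT
    return PixelClassMap(labels)


def segment_cells(
    classmap: PixelClassMap,
    min_area: int = 1200,
    max_area: int = 6500,
    min_nucleus_px: int = 25,
    thresholds: Sequence[float] = CANONICAL_THRESHOLDS,
) -> list[DetectedCell]:
    """Extract macrophage candidates from a pixel class map.

    Connected components of cell pixels (cytoplasm, nucleus or pigment)
    after morphological closing; components larger than ``max_area`` are
    split by watershed on the distance transform; components without at
    least ``min_nucleus_px`` nucleus pixels (non-macrophages) or outside
    the plausible area range are discarded.
    """
    labels = classmap.labels
    cell_mask = closing(labels != BACKGROUND, disk(2))
    comp = cc_label(cell_mask)
    out: list[DetectedCell] = []
    for region in regionprops(comp):
        # work inside the region's bounding box only
        y0, x0 = region.bbox[0], region.bbox[1]
        sub_mask = region.image
        sub_labels = labels[region.slice]
        if region.area > max_area:
            out.extend(
                _split_oversized(
                    sub_mask, sub_labels, min_area, max_area,
                    min_nucleus_px, thresholds, y0, x0,
                )
            )
        else:
            cell = _measure_component(
                sub_mask, sub_labels, min_area, min_nucleus_px, thresholds, y0, x0
            )
            if cell is not None:
                out.append(cell)
    out.sort(key=lambda c: (c.y, c.x))
    return out


def _measure_component(
    mask: np.ndarray,
    labels: np.ndarray,
    min_area: int,
    min_nucleus_px: int,
    thresholds: Sequence[float],
    y0: int = 0,
    x0: int = 0,
) -> DetectedCell | None:
    area = int(mask.sum())
    if area < min_area:
        return None
    if int(((labels == NUCLEUS) & mask).sum()) < min_nucleus_px:
        return None  # anucleate: not a macrophage
    pigment_px = int(((labels == PIGMENT) & mask).sum())
    frac = min(pigment_px / area, 1.0)
    ys, xs = np.nonzero(mask)
    return DetectedCell(
        x=float(xs.mean() + x0),
        y=float(ys.mean() + y0),
        cell_area=area,
        pigment_fraction=frac,
        grade=grade_from_content(frac, thresholds),
    )


def _split_oversized(
    mask: np.ndarray,
    labels: np.ndarray,
    min_area: int,
    max_area: int,
    min_nucleus_px: int,
    thresholds: Sequence[float],
    y0: int = 0,
    x0: int = 0,
) -> list[DetectedCell]:
    """Watershed split of touching cells on the distance transform."""
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=40, labels=mask, exclude_border=False)
    if len(peaks) < 2:
        cell = _measure_component(
            mask, labels, min_area, min_nucleus_px, thresholds, y0, x0
        )
        return [cell] if cell is not None else []
    markers = np.zeros(mask.shape, dtype=int)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    ws = watershed(-dist, markers, mask=mask)
    cells = []
    for i in range(1, len(peaks) + 1):
        cell = _measure_component(
            ws == i, labels, min_area, min_nucleus_px, thresholds, y0, x0
        )
        if cell is not None:
            cells.append(cell)
    return cells


def score_image(
    image: np.ndarray,
    slide_id: str,
    stain: str = "prussian_blue",
    color_params: ColorParams = ColorParams(),
    min_area: int = 1200,
    max_area: int = 6500,
    min_nucleus_px: int = 25,
    thresholds: Sequence[float] = CANONICAL_THRESHOLDS,
    min_cells: int = 300,
    allow_fewer: bool = True,
    cutoff: float = 75.0,
) -> tuple[list[CellAnnotation], ThsRecord]:
    """Full image pipeline: classify pixels, segment, grade, compute THS.

    Emits the detections as an annotation set under the reserved rater id
    ``"algorithm"`` plus the slide's algorithmic THS record.
    """
    classmap = classify_pixels(image, stain, color_params)
    detections = segment_cells(classmap, min_area, max_area, min_nucleus_px, thresholds)
    annotations = [
        CellAnnotation(slide_id, "algorithm", d.x, d.y, d.grade) for d in detections
    ]
    record = compute_ths(
        annotations, min_cells=min_cells, allow_fewer=allow_fewer, cutoff=cutoff
    )
    return annotations, record
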