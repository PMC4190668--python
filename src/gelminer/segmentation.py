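"""Candidate-segment production from a raw figure.

Two detectors run side by side:

* a baseline layout detector — Otsu binarization followed by 4-connected
  component labeling (4-connectivity avoids bridging adjacent gel lanes
  through corner pixels), with a light horizontal closing so that glyphs
  of one word merge into a single segment;
* a very simple rectangle detector for axis-aligned boxes with low
  internal contrast (gels often survive only as faint outlines after
  binarization): Sobel edge magnitude → connected edge outlines → accept
  a candidate box if its perimeter is well covered by edge pixels and
  its interior intensity is near-uniform.

Their outputs are merged with duplicate suppression: when boxes overlap
at IoU > 0.8 the rectangle-detector box wins.

Text recognition is delegated to a pluggable OCR adapter; a segment is
called TEXT when the adapter returns at least one character at
confidence >= 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .figure_model import (
    BoundingBox,
    FigureImage,
    Segment,
    SegmentKind,
    SegmentSource,
)

__all__ = [
    "SegmentationConfig",
    "OCRAdapter",
    "MockOCR",
    "NullOCR",
    "TesseractOCR",
    "detect_segments",
    "detect_rectangles",
    "merge_segments",
    "run_ocr",
    "segment_figure",
]

logger = logging.getLogger(__name__)

_TEXT_CONFIDENCE = 0.5
_DUPLICATE_IOU = 0.8


@dataclass(frozen=True)
class SegmentationConfig:
    binarize_threshold: int | None = None  # None = Otsu
    min_segment_area: int = 100
    rect_edge_min_len: int = 40
    rect_fill_tolerance: float = 0.12
    ocr_enabled: bool = False
    close_width: int = 7  # horizontal closing to merge word glyphs

    def __post_init__(self) -> None:
        if self.min_segment_area < 1:
            raise ValueError("min_segment_area must be >= 1")
        if not 0.0 <= self.rect_fill_tolerance <= 1.0:
            raise ValueError("rect_fill_tolerance must be in [0, 1]")


class OCRAdapter(Protocol):
    """Contract: (image crop, box) -> (text, confidence in [0, 1])."""

    def recognize(
        self, crop: np.ndarray, bbox: BoundingBox | None = None
    ) -> tuple[str, float]: ...


class NullOCR:
    """Adapter that recognizes nothing (OCR disabled)."""

    def recognize(self, crop, bbox=None):
        return "", 0.0


class MockOCR:
    """Deterministic test adapter mapping bounding boxes to fixed text."""

    def __init__(self, by_bbox: dict[tuple[int, int, int, int], str]):
        self.by_bbox = dict(by_bbox)

    def recognize(self, crop, bbox=None):
        if bbox is not None and bbox.as_tuple() in self.by_bbox:
            return self.by_bbox[bbox.as_tuple()], 1.0
        return "", 0.0


class TesseractOCR:
    """Optional adapter around pytesseract; import fails lazily."""

    def __init__(self) -> None:
        import pytesseract  # noqa: F401 — deferred dependency check

        self._pytesseract = pytesseract

    def recognize(self, crop, bbox=None):
        from PIL import Image

        try:
            text = self._pytesseract.image_to_string(Image.fromarray(crop))
        except Exception as exc:  # engine failure is never fatal
            logger.warning("OCR engine failure: %s", exc)
            return "", 0.0
        text = text.strip()
        return text, 1.0 if text else 0.0


def _binarize(gray: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Foreground mask: pixels darker than the (auto) threshold."""
    if gray.min() == gray.max():
        return np.zeros_like(gray, dtype=bool)
    thr = cfg.binarize_threshold
    if thr is None:
        thr = filters.threshold_otsu(gray)
    return gray <= thr


def _sort_segments(segments: list[Segment]) -> list[Segment]:
    return sorted(segments, key=lambda s: (s.bbox.y0, s.bbox.x0, s.bbox.as_tuple()))


def detect_segments(fig: FigureImage, cfg: SegmentationConfig = SegmentationConfig()) -> list[Segment]:
    """Baseline detector: connected non-background regions above
    ``min_segment_area``, ordered top-to-bottom then left-to-right."""
    gray = fig.gray()
    mask = _binarize(gray, cfg)
    if cfg.close_width > 1:
        structure = np.ones((1, cfg.close_width), dtype=bool)
        mask = ndimage.binary_closing(mask, structure=structure)
    labels, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    segments: list[Segment] = []
    if n:
        for idx, sl in enumerate(ndimage.find_objects(labels)):
            if sl is None:
                continue
            area = int(np.sum(labels[sl] == idx + 1))
            if area < cfg.min_segment_area:
                continue
            bbox = BoundingBox(sl[1].start, sl[0].start, sl[1].stop, sl[0].stop)
            segments.append(
                Segment(
                    segment_id="",
                    bbox=bbox,
                    kind=SegmentKind.GRAPHIC,
                    source=SegmentSource.SEGMENTATION,
                )
            )
    segments = _sort_segments(segments)
    return [
        Segment(
            segment_id=f"{fig.image_id}:seg{i}",
            bbox=s.bbox,
            kind=s.kind,
            source=s.source,
        )
        for i, s in enumerate(segments)
    ]


def detect_rectangles(fig: FigureImage, cfg: SegmentationConfig = SegmentationConfig()) -> list[Segment]:
    """Complementary detector for low-internal-contrast rectangles.

    Edge outlines are labeled 8-connected; a component's bounding box is
    accepted if its longer side reaches ``rect_edge_min_len``, at least
    70% of the box perimeter is covered by edge pixels, and the interior
    standard deviation is at most ``rect_fill_tolerance * 255``.
    """
    gray = fig.gray().astype(np.float64) / 255.0
    if gray.min() == gray.max():
        return []
    edge_mag = filters.sobel(gray)
    edges = edge_mag > 0.05
    labels = measure.label(edges, connectivity=2)
    segments: list[Segment] = []
    for region in measure.regionprops(labels):
        y0, x0, y1, x1 = region.bbox
        w, h = x1 - x0, y1 - y0
        if max(w, h) < cfg.rect_edge_min_len or min(w, h) < 8:
            continue
        component = labels[y0:y1, x0:x1] == region.label
        if _perimeter_coverage(component) < 0.7:
            continue
        interior = fig.gray()[y0 + 2 : y1 - 2, x0 + 2 : x1 - 2]
        if interior.size == 0:
            continue
        if interior.std() > cfg.rect_fill_tolerance * 255.0:
            continue
        segments.append(
            Segment(
                segment_id="",
                bbox=BoundingBox(x0, y0, x1, y1),
                kind=SegmentKind.GRAPHIC,
                source=SegmentSource.RECTANGLE_DETECTOR,
            )
        )
    segments = _sort_segments(segments)
    return [
        Segment(
            segment_id=f"{fig.image_id}:rect{i}",
            bbox=s.bbox,
            kind=s.kind,
            source=s.source,
        )
        for i, s in enumerate(segments)
    ]


def _perimeter_coverage(component: np.ndarray) -> float:
    """Fraction of the component-bbox perimeter ring covered by the
    component, measured on a 2-pixel-wide band per side."""
    h, w = component.shape
    band = 2
    sides = [
        component[:band, :].any(axis=0),  # top: per column
        component[-band:, :].any(axis=0),  # bottom
        component[:, :band].any(axis=1),  # left: per row
        component[:, -band:].any(axis=1),  # right
    ]
    covered = sum(int(s.sum()) for s in sides)
    total = 2 * (h + w)
    return covered / total


def merge_segments(
    base: Sequence[Segment], rectangles: Sequence[Segment]
) -> list[Segment]:
    """Union with duplicate suppression: IoU > 0.8 keeps the
    rectangle-detector box."""
    kept = [
        s
        for s in base
        if not any(s.bbox.iou(r.bbox) > _DUPLICATE_IOU for r in rectangles)
    ]
    return _sort_segments([*kept, *rectangles])


def run_ocr(fig: FigureImage, seg: Segment, engine: OCRAdapter) -> str:
    """Recognize text in a TEXT segment; engine failures yield ''."""
    if seg.kind is not SegmentKind.TEXT:
        raise ValueError(f"run_ocr on non-TEXT segment {seg.segment_id!r}")
    try:
        text, _confidence = engine.recognize(fig.crop(seg.bbox), seg.bbox)
    except Exception as exc:
        logger.warning("OCR failed on %s: %s", seg.segment_id, exc)
        return ""
    return text


def segment_figure(
    fig: FigureImage,
    cfg: SegmentationConfig = SegmentationConfig(),
    ocr: OCRAdapter | None = None,
) -> list[Segment]:
    """Full segmentation pass: both detectors, merge, then TEXT/GRAPHIC
    calls via the OCR adapter (when enabled)."""
    merged = merge_segments(detect_segments(fig, cfg), detect_rectangles(fig, cfg))
    if not (cfg.ocr_enabled and ocr is not None):
        return merged
    out = []
    for seg in merged:
        try:
            text, confidence = ocr.recognize(fig.crop(seg.bbox), seg.bbox)
        except Exception as exc:
            logger.warning("OCR failed on %s: %s", seg.segment_id, exc)
            text, confidence = "", 0.0
        if confidence >= _TEXT_CONFIDENCE and any(not c.isspace() for c in text):
            out.append(
                Segment(
                    segment_id=seg.segment_id,
                    bbox=seg.bbox,
                    kind=SegmentKind.TEXT,
                    text=text,
                    source=seg.source,
                )
            )
        else:
            out.append(seg)
    return out
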