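"""Core data types for figures, segments and annotations.

Coordinate convention used throughout the package: pixel coordinates are
0-based with the origin at the top-left corner of the image, and bounding
boxes are half-open integer intervals — a box ``(x0, y0, x1, y1)`` covers
pixel columns ``x0 .. x1-1`` and rows ``y0 .. y1-1``, so its width is
exactly ``x1 - x0``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "BoundingBox",
    "FigureImage",
    "Segment",
    "SegmentKind",
    "SegmentSource",
    "PanelAnnotation",
    "FigureAnnotation",
    "FigureFormatError",
    "AnnotationError",
    "load_figure",
    "figure_from_array",
    "read_annotation",
    "write_annotation",
    "rgb_to_gray",
]

# ITU-R 601 luma weights; the conventional grayscale reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


class FigureFormatError(ValueError):
    """Raised for unreadable or corrupt image files (counted as skipped)."""


class AnnotationError(ValueError):
    """Raised for annotation JSON that violates the schema."""


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned half-open integer pixel box."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not all(isinstance(v, (int, np.integer)) for v in self.as_tuple()):
            raise ValueError(f"box coordinates must be integers: {self.as_tuple()}")
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate box: {self.as_tuple()}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"negative coordinates: {self.as_tuple()}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def translate(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def intersection_area(self, other: "BoundingBox") -> int:
        w = min(self.x1, other.x1) - max(self.x0, other.x0)
        h = min(self.y1, other.y1) - max(self.y0, other.y0)
        return max(0, w) * max(0, h)

    def iou(self, other: "BoundingBox") -> float:
        inter = self.intersection_area(other)
        union = self.area + other.area - inter
        return inter / union if union else 0.0

    def hull(self, other: "BoundingBox") -> "BoundingBox":
        return BoundingBox(
            min(self.x0, other.x0),
            min(self.y0, other.y0),
            max(self.x1, other.x1),
            max(self.y1, other.y1),
        )

    def contains_box(self, other: "BoundingBox") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and self.x1 >= other.x1
            and self.y1 >= other.y1
        )

    @staticmethod
    def hull_of(boxes: Iterable["BoundingBox"]) -> "BoundingBox":
        boxes = list(boxes)
        if not boxes:
            raise ValueError("hull of an empty set of boxes")
        return BoundingBox(
            min(b.x0 for b in boxes),
            min(b.y0 for b in boxes),
            max(b.x1 for b in boxes),
            max(b.y1 for b in boxes),
        )


class SegmentKind(str, enum.Enum):
    TEXT = "TEXT"
    GRAPHIC = "GRAPHIC"


class SegmentSource(str, enum.Enum):
    SEGMENTATION = "SEGMENTATION"
    RECTANGLE_DETECTOR = "RECTANGLE_DETECTOR"
    ANNOTATION = "ANNOTATION"


@dataclass(frozen=True)
class Segment:
    """A rectangular region of a figure — the unit of classification.

    ``text`` carries OCR output and is only meaningful for TEXT segments;
    GRAPHIC segments always have empty text. ``is_gel`` is an optional
    gold-standard flag carried by annotated corpora.
    """

    segment_id: str
    bbox: BoundingBox
    kind: SegmentKind
    text: str = ""
    source: SegmentSource = SegmentSource.SEGMENTATION
    is_gel: bool | None = None

    def __post_init__(self) -> None:
        if self.kind is SegmentKind.GRAPHIC and self.text:
            raise ValueError(
                f"segment {self.segment_id!r}: GRAPHIC segments must have empty text"
            )

    def with_text(self, text: str) -> "Segment":
        return replace(self, text=text)


@dataclass(frozen=True)
class FigureImage:
    """A figure raster: H×W×3 uint8 pixels plus an identifier."""

    image_id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H×W×3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def bbox(self) -> BoundingBox:
        return BoundingBox(0, 0, self.width, self.height)

    def crop(self, bbox: BoundingBox) -> np.ndarray:
        if not self.bbox.contains_box(bbox):
            raise ValueError(f"box {bbox.as_tuple()} outside image {self.width}×{self.height}")
        return self.pixels[bbox.y0 : bbox.y1, bbox.x0 : bbox.x1]

    def gray(self) -> np.ndarray:
        """Grayscale view (uint8) via ITU-R 601 luma."""
        return rgb_to_gray(self.pixels)


def rgb_to_gray(pixels: np.ndarray) -> np.ndarray:
    """round(0.299 R + 0.587 G + 0.114 B), returned as uint8."""
    if pixels.ndim == 2:
        return pixels.astype(np.uint8)
    return np.rint(pixels.astype(np.float64) @ _LUMA).clip(0, 255).astype(np.uint8)


@dataclass(frozen=True)
class PanelAnnotation:
    """A panel as member segment ids plus attributed label segment ids."""

    members: tuple[str, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("panel with no member segments")


@dataclass
class FigureAnnotation:
    """Segments and panels for one figure; the gold-standard container."""

    image_id: str
    segments: list[Segment] = field(default_factory=list)
    panels: list[PanelAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.segment_id for s in self.segments]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate segment_id: {dup}")
        known = set(ids)
        for i, panel in enumerate(self.panels):
            for sid in (*panel.members, *panel.labels):
                if sid not in known:
                    raise AnnotationError(
                        f"panels[{i}] references unknown segment_id {sid!r}"
                    )

    def segment(self, segment_id: str) -> Segment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(segment_id)

    def to_dict(self) -> dict:
        segs = []
        for s in self.segments:
            d = {
                "segment_id": s.segment_id,
                "bbox": list(s.bbox.as_tuple()),
                "kind": s.kind.value,
                "text": s.text,
                "source": s.source.value,
            }
            if s.is_gel is not None:
                d["is_gel"] = s.is_gel
            segs.append(d)
        return {
            "image_id": self.image_id,
            "segments": segs,
            "panels": [
                {"members": list(p.members), "labels": list(p.labels)}
                for p in self.panels
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FigureAnnotation":
        try:
            image_id = data["image_id"]
        except KeyError:
            raise AnnotationError("missing field 'image_id'") from None
        if not isinstance(image_id, str):
            raise AnnotationError("field 'image_id' must be a string")
        segments = []
        for i, sd in enumerate(data.get("segments", [])):
            where = f"segments[{i}]"
            try:
                bbox_vals = sd["bbox"]
                kind = sd["kind"]
                segment_id = sd["segment_id"]
            except KeyError as exc:
                raise AnnotationError(f"{where}: missing field {exc.args[0]!r}") from None
            if kind not in SegmentKind.__members__:
                raise AnnotationError(f"{where}.kind: invalid value {kind!r}")
            if not (isinstance(bbox_vals, (list, tuple)) and len(bbox_vals) == 4):
                raise AnnotationError(f"{where}.bbox: expected [x0, y0, x1, y1]")
            try:
                bbox = BoundingBox(*(int(v) for v in bbox_vals))
            except (TypeError, ValueError) as exc:
                raise AnnotationError(f"{where}.bbox: {exc}") from None
            source = sd.get("source", SegmentSource.ANNOTATION.value)
            if source not in SegmentSource.__members__:
                raise AnnotationError(f"{where}.source: invalid value {source!r}")
            try:
                segments.append(
                    Segment(
                        segment_id=str(segment_id),
                        bbox=bbox,
                        kind=SegmentKind[kind],
                        text=sd.get("text", ""),
                        source=SegmentSource[source],
                        is_gel=sd.get("is_gel"),
                    )
                )
            except ValueError as exc:
                raise AnnotationError(f"{where}: {exc}") from None
        panels = []
        for i, pd in enumerate(data.get("panels", [])):
            where = f"panels[{i}]"
            members = pd.get("members")
            if not members:
                raise AnnotationError(f"{where}.members: must be non-empty")
            panels.append(
                PanelAnnotation(
                    members=tuple(str(m) for m in members),
                    labels=tuple(str(l) for l in pd.get("labels", [])),
                )
            )
        return cls(image_id=image_id, segments=segments, panels=panels)


def load_figure(path: str | Path) -> FigureImage:
    """Read a PNG/JPEG/TIFF figure.

    Grayscale and palette images are promoted to 3 identical/expanded
    channels; alpha is composited over white. Unreadable or truncated
    files raise :class:`FigureFormatError` so batch runs can count them
    as skipped instead of aborting.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGBA", "LA", "PA"):
                background = Image.new("RGBA", im.size, (255, 255, 255, 255))
                im = Image.alpha_composite(background, im.convert("RGBA"))
            im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError, ValueError) as exc:
        raise FigureFormatError(f"cannot read image {path}: {exc}") from exc
    return FigureImage(image_id=path.stem, pixels=pixels)


def figure_from_array(image_id: str, pixels: np.ndarray) -> FigureImage:
    """Wrap a 2-D grayscale or H×W×3 array as a FigureImage."""
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return FigureImage(image_id=image_id, pixels=arr.astype(np.uint8))


def read_annotation(path: str | Path) -> FigureAnnotation:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"invalid JSON in {path}: {exc}") from exc
    return FigureAnnotation.from_dict(data)


def write_annotation(ann: FigureAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ann.to_dict(), fh, indent=2, ensure_ascii=False)
        fh.write("\n")


def segments_by_kind(
    segments: Sequence[Segment], kind: SegmentKind
) -> list[Segment]:
    return [s for s in segments if s.kind is kind]
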