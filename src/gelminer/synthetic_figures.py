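"""Seeded generator of multi-panel figures with exact ground truth.

Figures are laid out on a white canvas divided into four cells. A cell
holds at most one content item — a gel panel (a grid of gel strips with
column labels above and row labels to the left), or a distractor (bar
graph, line graph, photo-like patch, or text block) — so that objects in
different cells are always farther apart than the grouping and label
attribution thresholds. Inside a panel cell, gel strips sit within the
50 px adjacency range of their neighbors and gold labels within the
30/150 px attribution window; decoy labels are placed in other cells, so
they are guaranteed true negatives for label attribution.

Gel strips are light-gray rectangles (background ~180–220) carrying dark
Gaussian-blurred elliptical bands in a lane layout; the WHITE_ON_BLACK
style is the exact intensity inversion. Everything is driven by a
``numpy`` seeded generator: a fixed seed reproduces the corpus
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy import ndimage

from .figure_model import (
    BoundingBox,
    FigureAnnotation,
    FigureImage,
    PanelAnnotation,
    Segment,
    SegmentKind,
    SegmentSource,
    figure_from_array,
)

__all__ = [
    "GeneratorConfig",
    "generate_gel_segment",
    "generate_figure",
    "generate_corpus",
    "corpus_hash",
]

DARK_ON_LIGHT = "DARK_ON_LIGHT"
WHITE_ON_BLACK = "WHITE_ON_BLACK"
MIXED = "MIXED"

# Short strings typical of gel labels: gene symbols, cell lines,
# conditions, and +/− condition rows.
DEFAULT_LABEL_POOL = (
    "LOX", "ACTB", "GAPDH", "TP53", "MYC", "EGFR", "KRAS", "BCL2",
    "STAT3", "VIM", "CDH1", "actin", "tubulin", "p53",
    "MDA-MB-231", "NHEM", "HeLa", "A549",
    "0h", "6h", "24h", "48h", "WT", "KO", "ctrl", "+", "-", "+/-",
    "10uM", "50uM", "kDa",
)

DEFAULT_DISTRACTOR_MIX = {
    "bar_graph": 0.3,
    "line_graph": 0.3,
    "photo_like": 0.2,
    "text_block": 0.2,
}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_figures: int = 10
    figure_width: int = 640
    figure_height: int = 480
    gel_style: str = MIXED
    panel_rows: tuple[int, int] = (1, 2)
    panel_cols: tuple[int, int] = (2, 4)
    band_count: tuple[int, int] = (1, 8)
    noise_sd: float = 2.0
    gel_panel_prob: float = 0.35
    second_panel_prob: float = 0.15
    n_distractors: tuple[int, int] = (1, 3)
    distractor_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTRACTOR_MIX)
    )
    decoy_label_prob: float = 0.5
    font_size: tuple[int, int] = (10, 14)
    label_pool: tuple[str, ...] = DEFAULT_LABEL_POOL

    def __post_init__(self) -> None:
        if self.gel_style not in (DARK_ON_LIGHT, WHITE_ON_BLACK, MIXED):
            raise ValueError(f"unknown gel_style {self.gel_style!r}")
        total = sum(self.distractor_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("distractor_mix fractions must sum to 1")
        for lo, hi in (self.panel_rows, self.panel_cols, self.band_count, self.n_distractors):
            if hi < lo:
                raise ValueError("empty range in generator config")


def generate_gel_segment(
    width: int,
    height: int,
    style: str,
    rng: np.random.Generator,
    band_count: tuple[int, int] = (1, 8),
    noise_sd: float = 2.0,
) -> tuple[np.ndarray, dict]:
    """One gel-strip patch plus its truth record.

    DARK_ON_LIGHT: light-gray background (180–220) with dark elliptical
    bands at least 40 units darker at their centers, one band per lane.
    WHITE_ON_BLACK is the exact inversion generated from the same random
    draws, so equal sub-seeds give ``white == 255 - dark``.
    """
    if style not in (DARK_ON_LIGHT, WHITE_ON_BLACK):
        raise ValueError(f"style must be resolved, got {style!r}")
    background = int(rng.integers(180, 221))
    max_lanes = max(1, width // 12)
    n_bands = int(rng.integers(band_count[0], min(band_count[1], max_lanes) + 1))
    lane_w = width / n_bands
    yy, xx = np.mgrid[0:height, 0:width]
    patch = np.full((height, width), float(background))
    bands = []
    for lane in range(n_bands):
        cx = (lane + 0.5) * lane_w + rng.uniform(-0.1, 0.1) * lane_w
        cy = rng.uniform(0.3, 0.7) * height
        rx = max(2.0, 0.32 * lane_w)
        ry = max(2.0, rng.uniform(0.08, 0.2) * height)
        depth = rng.uniform(48.0, 75.0)
        patch -= depth * np.exp(
            -(((xx - cx) ** 2) / (2 * rx**2) + ((yy - cy) ** 2) / (2 * ry**2))
        )
        bands.append(
            {"cx": float(cx), "cy": float(cy), "rx": rx, "ry": ry, "depth": depth}
        )
    if noise_sd > 0:
        patch += rng.normal(0.0, noise_sd, size=patch.shape)
    patch = np.clip(np.rint(patch), 0, 255).astype(np.uint8)
    if style == WHITE_ON_BLACK:
        patch = (255 - patch.astype(np.int16)).astype(np.uint8)
    truth = {"style": style, "background": background, "bands": bands}
    return patch, truth


def _load_font(size: int) -> ImageFont.ImageFont:
    try:
        return ImageFont.load_default(size=size)
    except TypeError:  # very old Pillow: bitmap font, fixed size
        return ImageFont.load_default()


class _Canvas:
    """Grayscale canvas with text rendering and segment bookkeeping."""

    def __init__(self, width: int, height: int):
        self.image = Image.new("L", (width, height), 255)
        self.draw = ImageDraw.Draw(self.image)
        self.segments: list[Segment] = []
        self.panels: list[PanelAnnotation] = []
        self._n = 0

    def next_id(self, image_id: str) -> str:
        sid = f"{image_id}:s{self._n}"
        self._n += 1
        return sid

    def paste(self, patch: np.ndarray, x: int, y: int) -> BoundingBox:
        self.image.paste(Image.fromarray(patch), (x, y))
        return BoundingBox(x, y, x + patch.shape[1], y + patch.shape[0])

    def text(self, s: str, x: int, y: int, font) -> BoundingBox:
        """Render text with its top-left corner at (x, y); returns the
        tight box of the rendered glyphs."""
        l, t, r, b = self.draw.textbbox((0, 0), s, font=font)
        ox, oy = x - l, y - t
        self.draw.text((ox, oy), s, fill=0, font=font)
        return BoundingBox(x, y, max(x + 1, x + (r - l)), max(y + 1, y + (b - t)))


def _panel_into_cell(
    canvas: _Canvas,
    image_id: str,
    cell: BoundingBox,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    margin = 30
    label_w_budget = 44
    label_h_budget = 22
    ox = cell.x0 + margin + label_w_budget
    oy = cell.y0 + margin + label_h_budget
    avail_w = cell.x1 - margin - ox
    avail_h = cell.y1 - margin - oy

    gap = int(rng.integers(8, 25))  # within the 50 px adjacency range
    rows = int(rng.integers(cfg.panel_rows[0], cfg.panel_rows[1] + 1))
    cols = int(rng.integers(cfg.panel_cols[0], cfg.panel_cols[1] + 1))
    while cols > 1 and (avail_w - (cols - 1) * gap) // cols < 30:
        cols -= 1
    while rows > 1 and (avail_h - (rows - 1) * gap) // rows < 22:
        rows -= 1
    seg_w = int(rng.integers(30, (avail_w - (cols - 1) * gap) // cols + 1))
    seg_h = int(rng.integers(22, max(23, (avail_h - (rows - 1) * gap) // rows + 1)))

    style = cfg.gel_style
    if style == MIXED:
        style = WHITE_ON_BLACK if rng.random() < 0.25 else DARK_ON_LIGHT

    member_ids = []
    for i in range(rows):
        for j in range(cols):
            patch, _truth = generate_gel_segment(
                seg_w, seg_h, style, rng, cfg.band_count, cfg.noise_sd
            )
            x = ox + j * (seg_w + gap)
            y = oy + i * (seg_h + gap)
            bbox = canvas.paste(patch, x, y)
            sid = canvas.next_id(image_id)
            canvas.segments.append(
                Segment(sid, bbox, SegmentKind.GRAPHIC,
                        source=SegmentSource.ANNOTATION, is_gel=True)
            )
            member_ids.append(sid)

    font = _load_font(int(rng.integers(cfg.font_size[0], cfg.font_size[1] + 1)))
    label_ids = []
    # Column labels above each column, within the 30 px near rule.
    for j in range(cols):
        text = str(rng.choice(cfg.label_pool))
        gap_above = int(rng.integers(4, 16))
        l, t, r, b = canvas.draw.textbbox((0, 0), text, font=font)
        tw = max(1, min(r - l, seg_w + gap))
        x = ox + j * (seg_w + gap) + max(0, (seg_w - tw) // 2)
        y = oy - gap_above - max(1, b - t)
        bbox = canvas.text(text, x, y, font)
        sid = canvas.next_id(image_id)
        canvas.segments.append(
            Segment(sid, bbox, SegmentKind.TEXT, text=text,
                    source=SegmentSource.ANNOTATION, is_gel=False)
        )
        label_ids.append(sid)
    # Row labels to the left of each row.
    for i in range(rows):
        text = str(rng.choice(("+", "-", "WT", "KO", "ctrl", "24h", "0h")))
        gap_left = int(rng.integers(4, 16))
        l, t, r, b = canvas.draw.textbbox((0, 0), text, font=font)
        x = ox - gap_left - max(1, r - l)
        y = oy + i * (seg_h + gap) + max(0, (seg_h - (b - t)) // 2)
        bbox = canvas.text(text, max(cell.x0 + 2, x), y, font)
        sid = canvas.next_id(image_id)
        canvas.segments.append(
            Segment(sid, bbox, SegmentKind.TEXT, text=text,
                    source=SegmentSource.ANNOTATION, is_gel=False)
        )
        label_ids.append(sid)

    canvas.panels.append(
        PanelAnnotation(members=tuple(member_ids), labels=tuple(label_ids))
    )


def _distractor_into_cell(
    canvas: _Canvas,
    image_id: str,
    cell: BoundingBox,
    kind: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    margin = 30
    avail_w = max(24, cell.width - 2 * margin)
    avail_h = max(24, cell.height - 2 * margin)
    w = int(rng.integers(max(24, avail_w // 2), avail_w + 1))
    h = int(rng.integers(max(24, avail_h // 2), avail_h + 1))
    x = cell.x0 + margin
    y = cell.y0 + margin

    if kind == "text_block":
        font = _load_font(int(rng.integers(cfg.font_size[0], cfg.font_size[1] + 1)))
        words = [str(rng.choice(cfg.label_pool)) for _ in range(int(rng.integers(3, 7)))]
        text = " ".join(words)
        bbox = canvas.text(text, x, y, font)
        sid = canvas.next_id(image_id)
        canvas.segments.append(
            Segment(sid, bbox, SegmentKind.TEXT, text=text,
                    source=SegmentSource.ANNOTATION, is_gel=False)
        )
        return

    if kind == "bar_graph":
        patch = np.full((h, w), 255.0)
        patch[-3:, :] = 40  # x axis
        patch[:, :3] = 40  # y axis
        n_bars = int(rng.integers(3, 7))
        bar_w = max(3, (w - 10) // (2 * n_bars))
        for b in range(n_bars):
            bh = int(rng.uniform(0.25, 0.95) * (h - 6))
            bx = 6 + b * 2 * bar_w
            patch[h - 3 - bh : h - 3, bx : bx + bar_w] = rng.integers(30, 120)
    elif kind == "line_graph":
        patch = np.full((h, w), 255.0)
        patch[-3:, :] = 40
        patch[:, :3] = 40
        xs = np.arange(4, w - 2)
        knots = rng.uniform(0.1, 0.9, size=6) * (h - 8)
        ys = np.interp(xs, np.linspace(4, w - 2, 6), knots)
        for px, py in zip(xs, ys.astype(int)):
            patch[max(0, py - 1) : py + 1, px] = 20
    elif kind == "photo_like":
        base = rng.normal(size=(h, w))
        base = ndimage.gaussian_filter(base, sigma=rng.uniform(2.0, 5.0))
        lo, hi = base.min(), base.max()
        patch = 20 + 215 * (base - lo) / max(hi - lo, 1e-9)
    else:
        raise ValueError(f"unknown distractor kind {kind!r}")

    patch = np.clip(np.rint(patch), 0, 255).astype(np.uint8)
    bbox = canvas.paste(patch, x, y)
    sid = canvas.next_id(image_id)
    canvas.segments.append(
        Segment(sid, bbox, SegmentKind.GRAPHIC,
                source=SegmentSource.ANNOTATION, is_gel=False)
    )


def _decoy_label_into_cell(
    canvas: _Canvas,
    image_id: str,
    cell: BoundingBox,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    font = _load_font(int(rng.integers(cfg.font_size[0], cfg.font_size[1] + 1)))
    text = str(rng.choice(cfg.label_pool))
    x = int(cell.x0 + 4 + rng.integers(0, 20))
    y = int(cell.y0 + 4 + rng.integers(0, 12))
    bbox = canvas.text(text, x, y, font)
    sid = canvas.next_id(image_id)
    canvas.segments.append(
        Segment(sid, bbox, SegmentKind.TEXT, text=text,
                source=SegmentSource.ANNOTATION, is_gel=False)
    )


def generate_figure(
    cfg: GeneratorConfig, index: int
) -> tuple[FigureImage, FigureAnnotation]:
    """Deterministically generate figure ``index`` of the corpus.

    The per-figure RNG is seeded with (cfg.seed, index), so any figure
    can be regenerated independently of corpus size.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))
    image_id = f"synth{cfg.seed}_{index:05d}"
    canvas = _Canvas(cfg.figure_width, cfg.figure_height)

    half_w, half_h = cfg.figure_width // 2, cfg.figure_height // 2
    cells = [
        BoundingBox(0, 0, half_w, half_h),
        BoundingBox(half_w, 0, cfg.figure_width, half_h),
        BoundingBox(0, half_h, half_w, cfg.figure_height),
        BoundingBox(half_w, half_h, cfg.figure_width, cfg.figure_height),
    ]
    order = list(rng.permutation(len(cells)))

    n_panels = 0
    if rng.random() < cfg.gel_panel_prob:
        n_panels = 1
        if rng.random() < cfg.second_panel_prob:
            n_panels = 2
    n_distractors = int(
        rng.integers(cfg.n_distractors[0], cfg.n_distractors[1] + 1)
    )
    n_distractors = min(n_distractors, len(cells) - n_panels)

    kinds = list(cfg.distractor_mix)
    probs = np.array([cfg.distractor_mix[k] for k in kinds])
    cursor = 0
    for _ in range(n_panels):
        _panel_into_cell(canvas, image_id, cells[order[cursor]], cfg, rng)
        cursor += 1
    for _ in range(n_distractors):
        kind = str(rng.choice(kinds, p=probs))
        cell = cells[order[cursor]]
        _distractor_into_cell(canvas, image_id, cell, kind, cfg, rng)
        if rng.random() < cfg.decoy_label_prob:
            _decoy_label_into_cell(canvas, image_id, cell, cfg, rng)
        cursor += 1
    for i in range(cursor, len(cells)):
        if rng.random() < cfg.decoy_label_prob:
            _decoy_label_into_cell(canvas, image_id, cells[order[i]], cfg, rng)

    fig = figure_from_array(image_id, np.asarray(canvas.image))
    ann = FigureAnnotation(
        image_id=image_id, segments=canvas.segments, panels=canvas.panels
    )
    return fig, ann


def corpus_hash(image_hashes: Sequence[str]) -> str:
    return hashlib.sha256("".join(image_hashes).encode("ascii")).hexdigest()


def generate_corpus(cfg: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write ``n_figures`` (PNG, JSON) pairs plus a manifest.

    The manifest echoes the config, summarizes per-figure truth and
    carries a corpus-level hash for determinism checks. Returns the
    manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    total_segments = 0
    total_gel = 0
    for i in range(cfg.n_figures):
        fig, ann = generate_figure(cfg, i)
        img_path = out_dir / f"{fig.image_id}.png"
        Image.fromarray(fig.pixels).save(img_path, format="PNG")
        from .figure_model import write_annotation

        write_annotation(ann, out_dir / f"{fig.image_id}.json")
        n_gel = sum(1 for s in ann.segments if s.is_gel)
        total_segments += len(ann.segments)
        total_gel += n_gel
        entries.append(
            {
                "image_id": fig.image_id,
                "image_file": img_path.name,
                "annotation_file": f"{fig.image_id}.json",
                "n_segments": len(ann.segments),
                "n_gel_segments": n_gel,
                "n_panels": len(ann.panels),
                "image_sha256": hashlib.sha256(fig.pixels.tobytes()).hexdigest(),
            }
        )
    manifest = {
        "config": asdict(cfg),
        "figures": entries,
        "totals": {
            "n_figures": cfg.n_figures,
            "n_segments": total_segments,
            "n_gel_segments": total_gel,
            "gel_segment_fraction": (
                total_gel / total_segments if total_segments else 0.0
            ),
            "n_figures_with_panels": sum(1 for e in entries if e["n_panels"]),
        },
        "corpus_hash": corpus_hash([e["image_sha256"] for e in entries]),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
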