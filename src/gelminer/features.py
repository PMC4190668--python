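"""The 39-dimensional feature vector of an image segment.

Layout (canonical order, see :data:`FEATURE_NAMES`):

* 2 relative position features — bbox center over image width/height;
* 2 relative size features — bbox extent over image extent;
* 2 absolute size features — bbox width and height in pixels;
* 16 grayscale histogram fractions (equal-width bins over [0, 255]);
* 3 color features — mean red/green/blue channel intensity;
* 13 texture features — six Tamura-style statistics (coarseness,
  contrast, directionality, line-likeness, regularity, roughness) plus
  seven log-spaced radial spectral-power "ripple" bands;
* 1 character-count feature — recognized non-whitespace characters.

All features are deterministic functions of the segment pixels, its box
and its OCR text; only the two position features depend on where the
segment sits inside the figure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .figure_model import FigureImage, Segment, rgb_to_gray

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "N_FEATURES",
    "histogram_features",
    "texture_features",
    "extract_features",
    "ripple_band_index",
    "ripple_band_edges",
    "write_feature_csv",
    "read_feature_csv",
]

N_HIST_BINS = 16
N_TEXTURE = 13
N_RIPPLE_BANDS = 7
N_FEATURES = 39

TEXTURE_NAMES = (
    "coarseness",
    "contrast",
    "directionality",
    "line_likeness",
    "regularity",
    "roughness",
) + tuple(f"ripple_band_{i}" for i in range(N_RIPPLE_BANDS))

FEATURE_NAMES: tuple[str, ...] = (
    ("rel_x", "rel_y", "rel_w", "rel_h", "abs_w", "abs_h")
    + tuple(f"hist_{i}" for i in range(N_HIST_BINS))
    + ("color_r", "color_g", "color_b")
    + TEXTURE_NAMES
    + ("n_chars",)
)
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass(frozen=True)
class FeatureVector:
    rel_x: float
    rel_y: float
    rel_w: float
    rel_h: float
    abs_w: float
    abs_h: float
    hist: np.ndarray  # 16 fractions summing to 1
    color: np.ndarray  # mean R, G, B in [0, 255]
    texture: np.ndarray  # 13 reals
    n_chars: int

    def __post_init__(self) -> None:
        if self.hist.shape != (N_HIST_BINS,):
            raise ValueError(f"hist must have {N_HIST_BINS} bins")
        if self.color.shape != (3,):
            raise ValueError("color must have 3 entries")
        if self.texture.shape != (N_TEXTURE,):
            raise ValueError(f"texture must have {N_TEXTURE} entries")

    def to_array(self) -> np.ndarray:
        """Canonical length-39 float array in FEATURE_NAMES order."""
        arr = np.concatenate(
            [
                [self.rel_x, self.rel_y, self.rel_w, self.rel_h, self.abs_w, self.abs_h],
                self.hist,
                self.color,
                self.texture,
                [float(self.n_chars)],
            ]
        )
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite feature value")
        return arr

    def __len__(self) -> int:
        return N_FEATURES


def histogram_features(gray: np.ndarray) -> np.ndarray:
    """16 equal-width grayscale histogram fractions.

    Bin ``b`` counts intensities in ``[16b, 16b + 16)``; the last bin is
    closed at 255. Fractions sum to 1 for any non-empty region.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("histogram of an empty region")
    counts, _ = np.histogram(gray, bins=np.arange(0, 257, 16))
    return counts / gray.size


def _tamura_coarseness(g: np.ndarray) -> float:
    """Best-neighborhood-size statistic: mean over pixels of the window
    size 2**k maximizing the averaged-intensity difference between
    opposite neighborhoods."""
    h, w = g.shape
    kmax = max(1, min(5, int(np.floor(np.log2(min(h, w))))))
    best_e = np.zeros_like(g, dtype=float)
    best_k = np.zeros_like(g, dtype=float)
    for k in range(1, kmax + 1):
        size = 2**k
        a = ndimage.uniform_filter(g, size=size, mode="nearest")
        d = 2 ** (k - 1)
        eh = np.zeros_like(g)
        ev = np.zeros_like(g)
        if w > 2 * d:
            eh[:, d:-d] = np.abs(a[:, 2 * d :] - a[:, : -2 * d])
        if h > 2 * d:
            ev[d:-d, :] = np.abs(a[2 * d :, :] - a[: -2 * d, :])
        e = np.maximum(eh, ev)
        better = e > best_e + 1e-12
        best_e = np.where(better, e, best_e)
        best_k = np.where(better, float(k), best_k)
    return float(np.mean(2.0**best_k))


def _tamura_contrast(g: np.ndarray) -> float:
    sigma = g.std()
    if sigma < 1e-12:
        return 0.0
    m4 = np.mean((g - g.mean()) ** 4)
    kurtosis = m4 / sigma**4
    return float(sigma / kurtosis**0.25)


def _gradient_direction_histogram(g: np.ndarray, n_bins: int = 16):
    gy, gx = np.gradient(g)
    mag = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx) % np.pi  # orientation, not direction
    weights = np.where(mag > 1e-9, mag, 0.0)
    total = weights.sum()
    if total < 1e-12:
        return None, None, None
    hist, edges = np.histogram(theta, bins=n_bins, range=(0.0, np.pi), weights=weights)
    return hist / total, edges, (theta, weights, total)


def _tamura_directionality(g: np.ndarray) -> float:
    """Peakedness of the gradient-orientation histogram (sum of squared
    bin fractions, rescaled so a uniform histogram maps to 0 and a
    single-bin histogram to 1); 0 for constant images."""
    p, _, _ = _gradient_direction_histogram(g)
    if p is None:
        return 0.0
    n = p.size
    return float((np.sum(p**2) - 1.0 / n) / (1.0 - 1.0 / n))


def _tamura_line_likeness(g: np.ndarray) -> float:
    """Orientation coherence: magnitude-weighted mean of cos(2Δθ) against
    the dominant orientation, clipped to [0, 1]."""
    p, edges, raw = _gradient_direction_histogram(g)
    if p is None:
        return 0.0
    theta, weights, total = raw
    centers = (edges[:-1] + edges[1:]) / 2.0
    dominant = centers[int(np.argmax(p))]
    coherence = np.sum(weights * np.cos(2.0 * (theta - dominant))) / total
    return float(np.clip(coherence, 0.0, 1.0))


def _tamura_regularity(g: np.ndarray) -> float:
    """1 minus the relative spread of sub-image contrast over a 2×2
    partition; 1 for perfectly homogeneous texture."""
    h, w = g.shape
    quadrants = [
        g[: h // 2, : w // 2],
        g[: h // 2, w // 2 :],
        g[h // 2 :, : w // 2],
        g[h // 2 :, w // 2 :],
    ]
    contrasts = np.array([_tamura_contrast(q) for q in quadrants if q.size])
    mean = contrasts.mean()
    if mean < 1e-12:
        return 1.0
    return float(np.clip(1.0 - contrasts.std() / mean, 0.0, 1.0))


def ripple_band_edges() -> np.ndarray:
    """Log-spaced radial-frequency band edges in cycles/pixel.

    Seven bands spanning 1/64 cycles/pixel up to the 2-D Nyquist corner
    sqrt(2)/2; energy below the lowest edge is folded into band 0.
    """
    return np.geomspace(1.0 / 64.0, np.sqrt(2.0) / 2.0, N_RIPPLE_BANDS + 1)


def ripple_band_index(freq: float) -> int:
    """Band that a given radial frequency (cycles/pixel) falls into."""
    edges = ripple_band_edges()
    return int(np.clip(np.searchsorted(edges, freq, side="right") - 1, 0, N_RIPPLE_BANDS - 1))


def _ripple_bands(g: np.ndarray) -> np.ndarray:
    """Fractions of non-DC spectral power in 7 log-spaced radial bands."""
    f = np.fft.fft2(g - g.mean())
    power = np.abs(f) ** 2
    power[0, 0] = 0.0
    total = power.sum()
    if total < 1e-12:
        return np.zeros(N_RIPPLE_BANDS)
    fy = np.fft.fftfreq(g.shape[0])[:, None]
    fx = np.fft.fftfreq(g.shape[1])[None, :]
    radius = np.hypot(fy, fx)
    edges = ripple_band_edges()
    band = np.clip(np.searchsorted(edges, radius, side="right") - 1, 0, N_RIPPLE_BANDS - 1)
    out = np.zeros(N_RIPPLE_BANDS)
    np.add.at(out, band.ravel(), power.ravel())
    return out / total


def texture_features(gray: np.ndarray) -> np.ndarray:
    """13 texture statistics of a grayscale patch.

    Patches smaller than 16×16 are computed on a zero-padded 16×16
    canvas. A constant patch yields zero contrast and zero ripple power.
    """
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("texture_features expects a 2-D grayscale array")
    if g.shape[0] < 16 or g.shape[1] < 16:
        canvas = np.zeros((max(16, g.shape[0]), max(16, g.shape[1])))
        canvas[: g.shape[0], : g.shape[1]] = g
        g = canvas
    coarseness = _tamura_coarseness(g)
    contrast = _tamura_contrast(g)
    out = np.concatenate(
        [
            [
                coarseness,
                contrast,
                _tamura_directionality(g),
                _tamura_line_likeness(g),
                _tamura_regularity(g),
                coarseness + contrast,  # roughness
            ],
            _ripple_bands(g),
        ]
    )
    return out


def extract_features(fig: FigureImage, seg: Segment) -> FeatureVector:
    """Compute all 39 features of ``seg`` within ``fig``."""
    bbox = seg.bbox
    if not fig.bbox.contains_box(bbox):
        raise ValueError(
            f"segment {seg.segment_id!r} box {bbox.as_tuple()} outside image"
        )
    patch = fig.crop(bbox)
    gray = rgb_to_gray(patch)
    cx, cy = bbox.center
    return FeatureVector(
        rel_x=cx / fig.width,
        rel_y=cy / fig.height,
        rel_w=bbox.width / fig.width,
        rel_h=bbox.height / fig.height,
        abs_w=float(bbox.width),
        abs_h=float(bbox.height),
        hist=histogram_features(gray),
        color=patch.reshape(-1, 3).mean(axis=0).astype(np.float64),
        texture=texture_features(gray),
        n_chars=sum(1 for c in seg.text if not c.isspace()),
    )


def write_feature_csv(
    path: str | Path,
    rows: Iterable[tuple[str, FeatureVector, bool | None]],
) -> None:
    """Export (segment_id, features, is_gel) rows as CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["segment_id", *FEATURE_NAMES, "is_gel"])
        for segment_id, fv, is_gel in rows:
            label = "" if is_gel is None else int(is_gel)
            writer.writerow([segment_id, *(repr(float(v)) for v in fv.to_array()), label])


def read_feature_csv(path: str | Path):
    """Read a feature CSV back as (ids, X, y); y entries may be None."""
    ids: list[str] = []
    x_rows: list[list[float]] = []
    y: list[bool | None] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["segment_id", *FEATURE_NAMES, "is_gel"]:
            raise ValueError(f"unexpected feature CSV header in {path}")
        for row in reader:
            ids.append(row[0])
            x_rows.append([float(v) for v in row[1 : 1 + N_FEATURES]])
            y.append(None if row[-1] == "" else bool(int(row[-1])))
    return ids, np.array(x_rows, dtype=np.float64), y
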