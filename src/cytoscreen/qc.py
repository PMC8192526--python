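"""Digital pathology image quality control (focus, stain, cellularity gate).

A digitized smear that is out of focus, washed out, or nearly acellular
cannot be screened, whatever the downstream models do.  The QC gate tiles
the scan (nominal 6000 x 6000 pixel tiles at 0.25 um/pixel), computes per
tile:

* **focus** — variance of the 4-neighbour Laplacian response (sharp
  images have strong second derivatives at edges; defocus suppresses
  them);
* **contrast/stain** — normalized histograms of the hue, saturation and
  intensity channels in HSI space (I = (R+G+B)/3, S = 1 - min/I,
  geometric hue);
* **cellularity** — fraction of the tile covered by the dark (stained)
  Otsu class, a cheap surrogate for cell count on a bright-field
  background;

then summarizes the tile metrics into a slide feature vector and scores
it with a boosted classifier, yielding a qualified / unqualified verdict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import xgboost as xgb
from scipy.ndimage import convolve
from skimage.filters import threshold_otsu

__all__ = [
    "QCTile", "QCResult", "tile_image", "focus_score", "his_features",
    "cell_area_ratio", "tile_metrics", "slide_qc_features", "train_qc_gate",
    "qc_gate", "QC_TILE_SIZE",
]

#: Nominal QC tile side in pixels.
QC_TILE_SIZE = 6000

# 4-neighbour Laplacian stencil.
_LAPLACIAN = np.array([[0, 1, 0],
                       [1, -4, 1],
                       [0, 1, 0]], dtype=float)


@dataclass
class QCTile:
    """Per-tile quality metrics."""

    origin: tuple[int, int]           # (x, y), 0-based pixels
    size: tuple[int, int]             # (width, height) actually covered
    focus: float
    hue_hist: np.ndarray
    sat_hist: np.ndarray
    int_hist: np.ndarray
    cell_area_ratio: float
    truncated: bool = False           # edge tile smaller than nominal size


@dataclass
class QCResult:
    """Slide-level QC verdict with the evidence behind it."""

    slide_id: str
    tiles: list[QCTile]
    slide_features: np.ndarray
    verdict: str                      # "qualified" | "unqualified"
    verdict_prob: float               # P(qualified)

    def to_json(self) -> str:
        return json.dumps({
            "slide_id": self.slide_id,
            "n_tiles": len(self.tiles),
            "verdict": self.verdict,
            "verdict_prob": round(self.verdict_prob, 9),
            "per_tile": [{
                "origin": list(t.origin), "size": list(t.size),
                "focus": round(t.focus, 6),
                "cell_area_ratio": round(t.cell_area_ratio, 6),
                "truncated": t.truncated,
            } for t in self.tiles],
        }, sort_keys=True, separators=(",", ":"))


def tile_image(dims: tuple[int, int], tile_size: int = QC_TILE_SIZE
               ) -> list[tuple[int, int, int, int, bool]]:
    """Grid of (x, y, width, height, truncated) covering an image.

    ``dims`` is (width, height).  Edge tiles are truncated, never padded,
    and flagged.
    """
    w, h = dims
    if w <= 0 or h <= 0:
        raise ValueError(f"non-positive image dims: {dims}")
    tiles = []
    for y in range(0, h, tile_size):
        th = min(tile_size, h - y)
        for x in range(0, w, tile_size):
            tw = min(tile_size, w - x)
            tiles.append((x, y, tw, th, tw < tile_size or th < tile_size))
    return tiles


def focus_score(gray_tile: np.ndarray) -> float:
    """Variance of the 4-neighbour Laplacian response (larger = sharper)."""
    g = np.asarray(gray_tile, dtype=float)
    if g.ndim != 2:
        raise ValueError("focus_score expects a single-channel tile")
    if min(g.shape) < 3:
        raise ValueError(f"tile {g.shape} smaller than the Laplacian kernel")
    resp = convolve(g, _LAPLACIAN, mode="nearest")
    return float(resp.var())


def _rgb_to_hsi(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HSI conversion: I=(R+G+B)/3, S=1-min/I, geometric hue in [0, 1)."""
    x = np.asarray(rgb, dtype=float) / 255.0
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    i = (r + g + b) / 3.0
    minc = np.minimum(np.minimum(r, g), b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(i > 0, 1.0 - minc / np.maximum(i, 1e-12), 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        theta = np.arccos(np.clip(num / np.maximum(den, 1e-12), -1.0, 1.0))
    h = np.where(b > g, 2 * np.pi - theta, theta) / (2 * np.pi)
    h = np.where(den < 1e-12, 0.0, h)  # achromatic: hue undefined, bin 0
    return h, s, i


def his_features(rgb_tile: np.ndarray, n_bins: int = 32
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized hue / intensity / saturation histograms of a tile."""
    img = np.asarray(rgb_tile)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an RGB tile, got shape {img.shape}")
    h, s, i = _rgb_to_hsi(img)
    hists = []
    for channel in (h, i, s):
        hist, _ = np.histogram(channel, bins=n_bins, range=(0.0, 1.0 + 1e-9))
        hists.append(hist / channel.size)
    hue_hist, int_hist, sat_hist = hists
    return hue_hist, int_hist, sat_hist


def cell_area_ratio(gray_tile: np.ndarray) -> float:
    """Fraction of the tile in the dark (stained-cell) Otsu class.

    Papanicolaou-stained cells are darker than the bright-field
    background, so foreground = below-threshold.  A constant tile has no
    bimodality and returns 0 by convention.  Polarity can be flipped for
    inverted imagery.
    """
    g = np.asarray(gray_tile)
    if g.ndim != 2:
        raise ValueError("cell_area_ratio expects a single-channel tile")
    if np.unique(g).size < 2:
        return 0.0
    thr = threshold_otsu(g.astype(np.uint8) if g.dtype != np.uint8 else g)
    return float((g <= thr).mean())


def tile_metrics(rgb_tile: np.ndarray, origin: tuple[int, int] = (0, 0),
                 n_bins: int = 16, truncated: bool = False,
                 dark_foreground: bool = True) -> QCTile:
    """All QC metrics for one RGB tile."""
    img = np.asarray(rgb_tile)
    gray = img.astype(float) @ np.array([0.299, 0.587, 0.114])
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    ratio = cell_area_ratio(gray if dark_foreground else 255 - gray)
    hue_hist, int_hist, sat_hist = his_features(img, n_bins=n_bins)
    return QCTile(origin=origin, size=(img.shape[1], img.shape[0]),
                  focus=focus_score(gray), hue_hist=hue_hist,
                  sat_hist=sat_hist, int_hist=int_hist,
                  cell_area_ratio=ratio, truncated=truncated)


_QUANTS = (0.1, 0.5, 0.9)


def slide_qc_features(tiles: Sequence[QCTile]) -> np.ndarray:
    """Slide summary vector: quantiles+mean of focus (log1p) and
    cellularity, plus mean per-channel histograms."""
    if not tiles:
        raise ValueError("need at least one tile")
    focus = np.log1p([t.focus for t in tiles])
    ratio = np.array([t.cell_area_ratio for t in tiles])
    parts = [np.quantile(focus, _QUANTS), [focus.mean()],
             np.quantile(ratio, _QUANTS), [ratio.mean()],
             np.mean([t.hue_hist for t in tiles], axis=0),
             np.mean([t.int_hist for t in tiles], axis=0),
             np.mean([t.sat_hist for t in tiles], axis=0)]
    return np.concatenate(parts)


def train_qc_gate(feature_matrix: np.ndarray, qualified: Sequence[int],
                  seed: int = 0) -> xgb.XGBClassifier:
    """Boosted qualified/unqualified gate over slide QC feature vectors."""
    y = np.asarray(qualified, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("gate training needs qualified and unqualified slides")
    model = xgb.XGBClassifier(n_estimators=80, max_depth=3, learning_rate=0.3,
                              tree_method="hist", n_jobs=1, verbosity=0,
                              random_state=seed)
    model.fit(np.asarray(feature_matrix, dtype=float), y)
    return model


def qc_gate(tiles: Sequence[QCTile], model: xgb.XGBClassifier,
            slide_id: str = "", threshold: float = 0.5) -> QCResult:
    """Score a slide's tiles and emit the qualified/unqualified verdict."""
    if not tiles:
        raise ValueError("qc_gate needs at least one tile")
    if model is None or not hasattr(model, "predict_proba"):
        raise ValueError("qc_gate needs a trained gate model")
    feats = slide_qc_features(tiles)
    prob = float(model.predict_proba(feats.reshape(1, -1))[0, 1])
    verdict = "qualified" if prob >= threshold else "unqualified"
    return QCResult(slide_id=slide_id, tiles=list(tiles),
                    slide_features=feats, verdict=verdict, verdict_prob=prob)
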