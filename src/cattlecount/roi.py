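"""Region-of-interest extraction on a regular tile grid.

Frames are divided into 224×224-px squares; a pluggable classifier labels
each tile ``cattle`` or ``non_cattle`` and non-cattle tiles are zeroed
out. The trained CNN that performs this labelling in the field is out of
scope here — the classifier is a contract, with a ground-truth oracle, a
coat-color brightness heuristic, and constant classifiers provided.
"""

from __future__ import annotations

import importlib
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .config import RunConfig
from .image import RgbImage
from .scenes import SceneTruth

LABELS = ("cattle", "non_cattle", "unknown")

#: classifier contract: (tile pixels, (r0, r1, c0, c1) window) -> label
TileClassifier = Callable[[np.ndarray, tuple[int, int, int, int]], str]


class ContractViolationError(ValueError):
    """A tile classifier returned something outside the label set."""


class DimensionError(ValueError):
    pass


@dataclass(frozen=True)
class Tile:
    row: int
    col: int
    window: tuple[int, int, int, int]    # (r0, r1, c0, c1), half-open
    label: str = "unknown"


@dataclass
class TileGrid:
    tile_size: int
    n_rows: int
    n_cols: int
    tiles: list[Tile]
    image_shape: tuple[int, int]


@dataclass
class RoiImage:
    """Source frame with non-cattle tiles zeroed out."""

    pixels: np.ndarray                   # H×W×3 uint8, zeros outside ROI
    roi_mask: np.ndarray                 # boolean H×W, union of whole tiles
    source: Optional[RgbImage] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def tile_image(img: RgbImage | np.ndarray, tile_size: int = 224) -> TileGrid:
    """Cover the image with a regular grid anchored at (0, 0).

    Edge tiles are truncated rather than padded, so the windows are
    disjoint and cover every pixel exactly once.
    """
    pixels = img.pixels if isinstance(img, RgbImage) else np.asarray(img)
    H, W = pixels.shape[:2]
    if tile_size <= 0:
        raise DimensionError("tile size must be positive")
    if H < tile_size or W < tile_size:
        raise DimensionError(
            f"image {H}x{W} is smaller than one {tile_size}-px tile")
    n_rows = -(-H // tile_size)
    n_cols = -(-W // tile_size)
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            r0, c0 = r * tile_size, c * tile_size
            window = (r0, min(r0 + tile_size, H), c0, min(c0 + tile_size, W))
            tiles.append(Tile(row=r, col=c, window=window))
    return TileGrid(tile_size=tile_size, n_rows=n_rows, n_cols=n_cols,
                    tiles=tiles, image_shape=(H, W))


def build_roi(img: RgbImage | np.ndarray, grid: TileGrid,
              classifier: TileClassifier) -> RoiImage:
    """Zero out tiles the classifier does not label ``cattle``.

    ``unknown`` is treated as non-cattle: only positively identified
    tiles survive.
    """
    pixels = img.pixels if isinstance(img, RgbImage) else np.asarray(img)
    if pixels.shape[:2] != grid.image_shape:
        raise DimensionError("grid was built for a different image shape")
    out = np.zeros_like(pixels)
    roi_mask = np.zeros(grid.image_shape, dtype=bool)
    for tile in grid.tiles:
        r0, r1, c0, c1 = tile.window
        label = classifier(pixels[r0:r1, c0:c1], tile.window)
        if label not in LABELS:
            raise ContractViolationError(
                f"classifier returned {label!r}; expected one of {LABELS}")
        if label == "cattle":
            out[r0:r1, c0:c1] = pixels[r0:r1, c0:c1]
            roi_mask[r0:r1, c0:c1] = True
    return RoiImage(pixels=out, roi_mask=roi_mask,
                    source=img if isinstance(img, RgbImage) else None)


# ---------------------------------------------------------------------
# built-in classifiers
# ---------------------------------------------------------------------

def constant_accept(pixels: np.ndarray, window) -> str:
    return "cattle"


def constant_reject(pixels: np.ndarray, window) -> str:
    return "non_cattle"


def brightness_classifier(config: RunConfig) -> TileClassifier:
    """Label a tile cattle when enough pixels are near the coat color."""
    coat = np.array(config.coat_rgb, dtype=np.float32)

    def classify(pixels: np.ndarray, window) -> str:
        dist = np.abs(pixels.astype(np.float32) - coat).max(axis=2)
        frac = float((dist < config.coat_tolerance).mean())
        return "cattle" if frac >= config.coat_min_fraction else "non_cattle"

    return classify


def truth_oracle_classifier(truth: SceneTruth,
                            margin: int = 24) -> TileClassifier:
    """Label a tile cattle iff a ground-truth animal lies on or near it.

    ``margin`` (px) widens each footprint before the tile test: the
    elliptical truth footprint is the torso only, while a detector keys
    on the whole animal — head, legs, tail, shadow — which at 1 cm/px
    extends a couple of dozen pixels further. Set 0 for the literal
    footprint-touches-tile rule.
    """
    mask = truth.animal_mask()
    if margin > 0 and mask.any():
        from scipy.ndimage import distance_transform_edt
        mask = distance_transform_edt(~mask) <= margin

    def classify(pixels: np.ndarray, window) -> str:
        r0, r1, c0, c1 = window
        return "cattle" if mask[r0:r1, c0:c1].any() else "non_cattle"

    return classify


def resolve_classifier(name: str, config: RunConfig,
                       truth: Optional[SceneTruth] = None) -> TileClassifier:
    """Look up a built-in classifier by keyword, or import a dotted name.

    A dotted name must point at a callable ``factory(config) ->
    TileClassifier``.
    """
    if name == "accept":
        return constant_accept
    if name == "reject":
        return constant_reject
    if name == "brightness":
        return brightness_classifier(config)
    if name == "oracle":
        if truth is None:
            raise ValueError("oracle classifier needs scene ground truth")
        return truth_oracle_classifier(truth)
    if "." in name:
        module, _, attr = name.rpartition(".")
        factory = getattr(importlib.import_module(module), attr)
        return factory(config)
    raise ValueError(f"unknown classifier {name!r}")
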