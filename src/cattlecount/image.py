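"""The 8-bit RGB survey frame container and its metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image


@dataclass
class RgbImage:
    """An 8-bit RGB frame plus capture metadata.

    ``pixels`` is H×W×3 uint8. ``timestamp`` is seconds since an arbitrary
    survey epoch (chronological ordering is what matters downstream).
    """

    pixels: np.ndarray
    timestamp: float = 0.0
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    altitude_m: Optional[float] = None
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H×W×3 RGB array, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels).save(path)

    @classmethod
    def load(cls, path: str | Path, **meta) -> "RgbImage":
        with Image.open(path) as im:
            px = np.asarray(im.convert("RGB"), dtype=np.uint8)
        return cls(pixels=px, image_id=str(Path(path).name), **meta)
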