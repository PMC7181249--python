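"""Combining the six channel masks into the three final masks.

Each Y-threshold variant is ANDed with the M mask — but Y objects that
survive the AND anywhere are restored in full, so the M mask acts as an
object-level veto rather than a pixel-level one — then ORed with the C
mask and the custom-channel mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label

from .colorspace import MaskSet


@dataclass
class FusedMasks:
    """Final masks, one per Y-threshold variant.

    White ⇔ value below threshold, so ``final_quarter ⊆ final_half ⊆
    final_full``.
    """

    final_full: np.ndarray
    final_half: np.ndarray
    final_quarter: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"full": self.final_full, "half": self.final_half,
                "quarter": self.final_quarter}


def and_with_restore(y: np.ndarray, m: np.ndarray) -> np.ndarray:
    """AND two masks, then restore every Y object that survived at all.

    A connected component (8-connectivity) of ``y`` that intersects ``m``
    anywhere is kept verbatim; components disjoint from ``m`` vanish.
    """
    y = np.asarray(y, dtype=bool)
    m = np.asarray(m, dtype=bool)
    if y.shape != m.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {m.shape}")
    labels = label(y, connectivity=2)
    surviving = np.unique(labels[m & y])
    surviving = surviving[surviving != 0]
    if surviving.size == 0:
        return np.zeros_like(y)
    return np.isin(labels, surviving)


def fuse(masks: MaskSet) -> FusedMasks:
    """Final mask per Y variant: restore(Y ∧ M) ∨ C ∨ custom."""
    base = masks.c | masks.custom
    out = {}
    for name, y in masks.y_masks().items():
        out[name] = and_with_restore(y, masks.m) | base
    return FusedMasks(final_full=out["full"], final_half=out["half"],
                      final_quarter=out["quarter"])
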