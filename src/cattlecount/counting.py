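"""Per-image animal counting: shape filtering, cluster splitting and the
three-estimate arbitration.

Objects are 8-connected components of a fused mask. Small or small-and-
ragged objects are dropped; a terrain-elevation factor ev (1 / 1.25 /
1.5, keyed on mean object area) rescales the size rules; objects flagged
as multi-animal clusters are split by topology-preserving thinning
(round(20·ev) iterations) followed by a one-pixel erosion, and the
fragment census Ah (area > 100) and Sl (solidity < 0.5) yields the
cluster's animal count N = Ah + Sl − 1. One estimate is produced per
final mask, and the final count takes the highest estimate unless it
exceeds the second highest by more than three, in which case the second
highest wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.measure import label, regionprops
from skimage.morphology import erosion, footprint_rectangle, thin

from .config import RunConfig
from .fusion import FusedMasks


@dataclass
class SegObject:
    """One connected foreground component and its shape descriptors."""

    label_id: int
    area: int
    solidity: float
    centroid: tuple[float, float]            # (row, col)
    bbox: tuple[int, int, int, int]          # (min_row, min_col, max_row, max_col)
    touches_border: bool
    footprint: np.ndarray                    # boolean patch within bbox

    def footprint_in(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.footprint
        return out


@dataclass
class ImageEstimate:
    """The three per-threshold counts and the arbitrated final count."""

    estimates: dict[str, int]                # per mask variant
    evs: dict[str, float]
    final: int
    contributions: dict[str, list[int]] = field(default_factory=dict)


def label_objects(mask: np.ndarray) -> list[SegObject]:
    """8-connected components with exact area, solidity and border flag."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    labels = label(mask, connectivity=2)
    out = []
    for p in regionprops(labels):
        r0, c0, r1, c1 = p.bbox
        out.append(SegObject(
            label_id=p.label,
            area=int(p.area),
            solidity=float(p.solidity),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            bbox=(r0, c0, r1, c1),
            touches_border=bool(r0 == 0 or c0 == 0 or r1 == H or c1 == W),
            footprint=p.image.copy(),
        ))
    return out


def filter_objects(objs: Sequence[SegObject],
                   config: RunConfig = RunConfig()) -> list[SegObject]:
    """Drop objects with area < 2000, and those with area < 5000 and
    solidity < 0.7. Inequalities are strict: equality survives."""
    kept = []
    for o in objs:
        if o.area < config.min_object_area:
            continue
        if o.area < config.small_object_area and o.solidity < config.min_solidity:
            continue
        kept.append(o)
    return kept


def elevation_factor(objs: Sequence[SegObject],
                     config: RunConfig = RunConfig()) -> float:
    """Piecewise factor on mean object area compensating GSD drift.

    ev = 1 below 8000 px, 1.25 in [8000, 15000), 1.5 at or above 15000.
    With no objects there is no basis for rescaling and ev = 1.
    """
    if not objs:
        return config.ev_values[0]
    mean_area = float(np.mean([o.area for o in objs]))
    lo, hi = config.ev_area_breaks
    if mean_area < lo:
        return config.ev_values[0]
    if mean_area < hi:
        return config.ev_values[1]
    return config.ev_values[2]


def is_cluster(obj: SegObject, ev: float,
               config: RunConfig = RunConfig()) -> bool:
    """Does the object potentially contain more than one animal?"""
    return (obj.area > ev * config.cluster_area_high
            or obj.solidity < config.cluster_solidity_low
            or (obj.area > ev * config.cluster_area_low
                and obj.solidity < config.cluster_solidity_high))


def _fragment_census(fragments: Sequence, config: RunConfig) -> tuple[int, int]:
    ah = sum(1 for f in fragments if f.area > config.fragment_min_area)
    sl = sum(1 for f in fragments if f.solidity < config.fragment_max_solidity)
    return ah, sl


def animals_from_census(ah: int, sl: int,
                        config: RunConfig = RunConfig()) -> int:
    """N = Ah + Sl − 1, floored at one animal per surviving object.

    ``additive`` mode instead adds any extra fragments on top of the one
    animal the object already represents.
    """
    if config.n_formula == "additive":
        return 1 + max(0, ah + sl - 1)
    return max(1, ah + sl - 1)


def cluster_count(obj: SegObject, ev: float,
                  config: RunConfig = RunConfig()) -> int:
    """Number of animals attributed to one object.

    Non-clusters count one. Clusters are thinned for round(20·ev)
    iterations and eroded by one pixel (3×3 square); the fragment census
    of the result feeds N = Ah + Sl − 1.
    """
    if not is_cluster(obj, ev, config):
        return 1
    n_iter = int(round(config.thinning_scale * ev))
    patch = np.pad(obj.footprint, 2)          # room for the 3×3 erosion
    thinned = thin(patch, max_num_iter=n_iter)
    eroded = erosion(thinned, footprint_rectangle((3, 3)))
    if not eroded.any():
        # morphology erased the object completely; by default it still
        # stands for one animal, optionally for none
        return 1 if config.empty_object_policy == "count_one" else 0
    fragments = regionprops(label(eroded, connectivity=2))
    ah, sl = _fragment_census(fragments, config)
    return animals_from_census(ah, sl, config)


def count_image(fused: FusedMasks,
                config: RunConfig = RunConfig()) -> ImageEstimate:
    """Label → filter → ev → per-object counts, for each final mask."""
    estimates: dict[str, int] = {}
    evs: dict[str, float] = {}
    contributions: dict[str, list[int]] = {}
    for name, mask in fused.as_dict().items():
        objs = filter_objects(label_objects(mask), config)
        ev = elevation_factor(objs, config)
        counts = [cluster_count(o, ev, config) for o in objs]
        estimates[name] = int(sum(counts))
        evs[name] = ev
        contributions[name] = counts
    final = final_estimate(list(estimates.values()), config)
    return ImageEstimate(estimates=estimates, evs=evs, final=final,
                         contributions=contributions)


def final_estimate(estimates: Sequence[int],
                   config: RunConfig = RunConfig()) -> int:
    """Highest estimate, unless it is more than three units above the
    second highest — then the second highest is taken."""
    if not estimates:
        raise ValueError("need at least one estimate")
    ordered = sorted(estimates, reverse=True)
    if len(ordered) == 1:
        return int(ordered[0])
    if ordered[0] - ordered[1] > config.final_margin:
        return int(ordered[1])
    return int(ordered[0])
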