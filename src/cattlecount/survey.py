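"""Pairwise frame registration and sequential overlap de-duplication.

Frames overlap by ~70%, so each animal appears in several frames. Frames
are processed chronologically: objects in a border band are removed but
their world positions stored; objects falling in regions already covered
by earlier frames are removed unless they match a stored border object,
in which case they are counted and the stored entry consumed.

Feature matching uses ORB keypoints with a RANSAC-fitted projective
transform as the primary detector and falls back to phase
cross-correlation (translation-only) when fewer than the configured
minimum of points match; surveys generated synthetically can also use
their exact ground-truth transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.registration import phase_cross_correlation
from skimage.transform import ProjectiveTransform, warp

from .config import RunConfig
from .counting import ImageEstimate, SegObject
from .image import RgbImage


class RegistrationError(RuntimeError):
    pass


class SurveyOrderError(ValueError):
    pass


@dataclass
class PairTransform:
    """Planar projective map from source-frame to target-frame coordinates
    (x, y) — note shapely/transform convention, i.e. (col, row)."""

    source_id: str
    target_id: str
    matrix: np.ndarray                     # 3×3, normalized
    n_matched_points: int
    detector_used: str                     # primary | fallback | truth

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("transform must be an invertible 3x3 matrix")
        self.matrix = m / m[2, 2]

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        h = np.hstack([xy, np.ones((len(xy), 1))]) @ self.matrix.T
        return h[:, :2] / h[:, 2:3]


def _translation_matrix(dx: float, dy: float) -> np.ndarray:
    m = np.eye(3)
    m[0, 2], m[1, 2] = dx, dy
    return m


def register_pair(a: RgbImage, b: RgbImage,
                  config: RunConfig = RunConfig(),
                  truth_translation: Optional[tuple[float, float]] = None
                  ) -> PairTransform:
    """Estimate the transform mapping frame ``a`` coordinates into ``b``.

    ``truth_translation`` is the (drow, dcol) of a relative to b from a
    synthetic survey; when given (or when the backend is "truth") it is
    used directly.
    """
    if config.registration_backend == "truth":
        if truth_translation is None:
            raise RegistrationError("truth backend needs a known translation")
        dr, dc = truth_translation
        return PairTransform(a.image_id, b.image_id,
                             _translation_matrix(dc, dr),
                             n_matched_points=0, detector_used="truth")

    ga = rgb2gray(a.pixels)
    gb = rgb2gray(b.pixels)
    result = None
    if config.registration_backend == "orb":
        result = _register_orb(ga, gb, config)
    if result is not None:
        matrix, n_inliers = result
        if n_inliers >= config.min_matches:
            return PairTransform(a.image_id, b.image_id, matrix,
                                 n_matched_points=n_inliers,
                                 detector_used="primary")
    # fallback: translation by phase correlation, validated by overlap
    # correlation so uncorrelated images fail loudly
    shift, _, _ = phase_cross_correlation(gb, ga, normalization=None)
    dr, dc = float(shift[0]), float(shift[1])
    matrix = _translation_matrix(dc, dr)
    score = _overlap_score(ga, gb, dr, dc)
    if score < config.min_registration_score:
        raise RegistrationError(
            f"both detectors failed between {a.image_id!r} and "
            f"{b.image_id!r} (overlap correlation {score:.3f})")
    return PairTransform(a.image_id, b.image_id, matrix,
                         n_matched_points=0, detector_used="fallback")


def _register_orb(ga: np.ndarray, gb: np.ndarray,
                  config: RunConfig) -> Optional[tuple[np.ndarray, int]]:
    try:
        orb_a = ORB(n_keypoints=500, fast_threshold=0.05)
        orb_a.detect_and_extract(ga)
        orb_b = ORB(n_keypoints=500, fast_threshold=0.05)
        orb_b.detect_and_extract(gb)
    except (RuntimeError, ValueError):
        return None
    matches = match_descriptors(orb_a.descriptors, orb_b.descriptors,
                                cross_check=True)
    if len(matches) < max(4, config.min_matches):
        return None
    # keypoints are (row, col); transforms want (x, y)
    src = orb_a.keypoints[matches[:, 0]][:, ::-1]
    dst = orb_b.keypoints[matches[:, 1]][:, ::-1]
    try:
        model, inliers = ransac((src, dst), ProjectiveTransform,
                                min_samples=4, residual_threshold=2,
                                max_trials=500, rng=0)
    except (ValueError, np.linalg.LinAlgError):
        return None
    if model is None or inliers is None:
        return None
    return np.asarray(model.params), int(inliers.sum())


def _overlap_score(ga: np.ndarray, gb: np.ndarray,
                   dr: float, dc: float) -> float:
    """Pearson correlation of the overlapping region after the shift."""
    H, W = ga.shape
    r0, r1 = max(0, int(dr)), min(H, H + int(dr))
    c0, c1 = max(0, int(dc)), min(W, W + int(dc))
    if r1 - r0 < 8 or c1 - c0 < 8:
        return 0.0
    pa = ga[r0 - int(dr):r1 - int(dr), c0 - int(dc):c1 - int(dc)]
    pb = gb[r0:r1, c0:c1]
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    denom = np.sqrt((pa ** 2).sum() * (pb ** 2).sum())
    return float((pa * pb).sum() / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------
# sequential de-duplication
# ---------------------------------------------------------------------

@dataclass
class CountedObject:
    """Minimal object view the de-dup stage needs: where it is and how
    many animals it stands for."""

    count: int
    centroid: tuple[float, float]          # (row, col) in frame coords
    bbox: tuple[float, float, float, float]  # (min_row, min_col, max_row, max_col)


@dataclass
class FrameRecord:
    image: RgbImage
    objects: list[CountedObject]
    shape: tuple[int, int]


@dataclass
class FrameTallyRow:
    image_id: str
    raw: int
    border_removed: int
    overlap_removed: int
    credited: int

    @property
    def adjusted(self) -> int:
        return self.raw - self.border_removed - self.overlap_removed + self.credited


@dataclass
class SurveyTally:
    rows: list[FrameTallyRow]
    total: int

    def to_dict(self) -> dict:
        return {"total": self.total,
                "frames": [{"image_id": r.image_id, "raw": r.raw,
                            "border_removed": r.border_removed,
                            "overlap_removed": r.overlap_removed,
                            "credited": r.credited,
                            "adjusted": r.adjusted} for r in self.rows]}


def objects_from_segmentation(objs: Sequence[SegObject],
                              counts: Sequence[int]) -> list[CountedObject]:
    return [CountedObject(count=c, centroid=o.centroid,
                          bbox=(o.bbox[0], o.bbox[1], o.bbox[2], o.bbox[3]))
            for o, c in zip(objs, counts)]


def objects_from_truth(truth, merge_clusters: bool = False
                       ) -> list[CountedObject]:
    """Build de-dup inputs straight from scene ground truth.

    With ``merge_clusters`` each cluster becomes one multi-animal object
    (as the segmentation stage would see it); otherwise one object per
    animal.
    """
    if not merge_clusters:
        return [CountedObject(count=1,
                              centroid=a.center,
                              bbox=a.bbox())
                for a in truth.animals]
    groups: dict[int, list] = {}
    for a in truth.animals:
        groups.setdefault(a.cluster_id, []).append(a)
    out = []
    for members in groups.values():
        boxes = np.array([m.bbox() for m in members])
        centroid = (float(np.mean([m.center[0] for m in members])),
                    float(np.mean([m.center[1] for m in members])))
        out.append(CountedObject(
            count=len(members), centroid=centroid,
            bbox=(float(boxes[:, 0].min()), float(boxes[:, 1].min()),
                  float(boxes[:, 2].max()), float(boxes[:, 3].max()))))
    return out


def _in_border_band(obj: CountedObject, shape: tuple[int, int],
                    band: int) -> bool:
    r0, c0, r1, c1 = obj.bbox
    H, W = shape
    return (r0 < band or c0 < band or r1 > H - band or c1 > W - band)


def dedup_survey(records: Sequence[FrameRecord],
                 transforms: Sequence[PairTransform],
                 config: RunConfig = RunConfig()) -> SurveyTally:
    """Tally a survey, counting each animal once.

    ``transforms[i]`` maps frame i coordinates into the shared world
    frame (frame 0's system). Frames must be in chronological order.
    """
    times = [r.image.timestamp for r in records]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise SurveyOrderError("frames are not in chronological order")
    if len(transforms) != len(records):
        raise RegistrationError("need one frame→world transform per frame")

    covered = None                         # union of processed footprints
    stored: list[dict] = []                # border objects awaiting credit
    rows: list[FrameTallyRow] = []
    band = config.border_band
    tol = config.carryover_tolerance

    for rec, tf in zip(records, transforms):
        H, W = rec.shape
        corners = tf.apply(np.array([[0, 0], [W, 0], [W, H], [0, H]], float))
        footprint = Polygon(corners)
        raw = border_removed = overlap_removed = credited = 0
        in_overlap: list[tuple] = []
        for obj in rec.objects:
            raw += obj.count
            world_xy = tf.apply(np.array([[obj.centroid[1],
                                           obj.centroid[0]]]))[0]
            if _in_border_band(obj, rec.shape, band):
                border_removed += obj.count
                # store a position only for objects awaiting their first
                # count: centroid inside this frame (seen whole) and not in
                # already-covered territory (trailing-edge borders were
                # counted, or stored, in an earlier frame)
                cr, cc_ = obj.centroid
                if (0 <= cr < H and 0 <= cc_ < W
                        and (covered is None
                             or not covered.covers(Point(world_xy)))):
                    stored.append({"xy": world_xy, "count": obj.count})
                continue
            if covered is not None and covered.covers(Point(world_xy)):
                overlap_removed += obj.count
                in_overlap.append((obj, world_xy))
        credited = _credit_carryovers(in_overlap, stored, tol)
        rows.append(FrameTallyRow(image_id=rec.image.image_id, raw=raw,
                                  border_removed=border_removed,
                                  overlap_removed=overlap_removed,
                                  credited=credited))
        covered = footprint if covered is None else unary_union(
            [covered, footprint])

    total = sum(r.adjusted for r in rows)
    return SurveyTally(rows=rows, total=total)


def _credit_carryovers(in_overlap: Sequence[tuple], stored: list[dict],
                       tol: float) -> int:
    """Match overlap-region objects to stored border positions.

    Greedy assignment by increasing distance, each object and each stored
    entry used at most once, within the tolerance radius. Matched objects
    are counted (credited) with their current count; their stored entries
    are consumed.
    """
    pairs = []
    for i, (obj, xy) in enumerate(in_overlap):
        for j, entry in enumerate(stored):
            d = float(np.hypot(*(entry["xy"] - xy)))
            if d <= tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_obj: set[int] = set()
    used_entry: set[int] = set()
    credited = 0
    for d, i, j in pairs:
        if i in used_obj or j in used_entry:
            continue
        used_obj.add(i)
        used_entry.add(j)
        credited += in_overlap[i][0].count
    for j in sorted(used_entry, reverse=True):
        del stored[j]
    return credited


def chain_to_world(pairs: Sequence[PairTransform]) -> list[PairTransform]:
    """Compose consecutive-pair transforms (i → i+1) into frame→world
    (frame 0) transforms for all frames."""
    out = [PairTransform("frame0", "world", np.eye(3), 0, "truth")]
    acc = np.eye(3)
    for p in pairs:
        # frame i+1 -> i is the inverse of i -> i+1
        acc = acc @ np.linalg.inv(p.matrix)
        out.append(PairTransform(p.target_id, "world", acc, p.n_matched_points,
                                 p.detector_used))
    return out
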