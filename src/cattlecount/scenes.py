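"""Ground-truthed synthetic pasture scenes and overlapping UAV surveys.

Scenes emulate nadir UAV frames at ~1 cm/pixel ground sample distance:
light-coated cattle rendered as shaded, anti-aliased ellipses of ~13,000
pixels (calves at a quarter of that), on heterogeneous pasture/soil
backgrounds, optionally with white-roof sheds, light-blue feeders and
trees as distractors. Surveys are sequences of frames cropped from a
single rendered world strip so the exact inter-frame transforms and a
global animal registry are known.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .image import RgbImage


class CapacityError(ValueError):
    """Requested animal load cannot be placed in the scene."""


class ParameterError(ValueError):
    """Survey geometry parameters are inconsistent."""


BACKGROUND_PRESETS: dict[str, tuple[int, int, int]] = {
    "green_pasture": (95, 138, 68),
    "dry_pasture": (188, 178, 122),
    "bare_soil": (150, 102, 72),
    "mixed": (140, 150, 95),
}

#: semi-axis ranges (px) giving a mean adult area of ~13,300 px
DEFAULT_ADULT_AXES = ((80.0, 100.0), (42.0, 52.0))


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``cluster_size_distribution`` maps cluster sizes 1..8 to probabilities;
    animals are grouped into clusters drawn from it until ``n_animals`` is
    reached. ``calf_fraction`` is the probability that an adult has a calf
    rendered touching it (calves are additional truth records at a quarter
    of the adult area).
    """

    width: int = 1024
    height: int = 1024
    background_kind: str = "green_pasture"
    background_mean_rgb: Optional[tuple[int, int, int]] = None
    noise_sd: float = 6.0
    n_animals: int = 6
    cluster_size_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 1.0})
    calf_fraction: float = 0.0
    animal_axis_px: tuple[tuple[float, float], tuple[float, float]] = (
        DEFAULT_ADULT_AXES)
    coat_mean_rgb: tuple[int, int, int] = (232, 226, 212)
    distractors: frozenset[str] = frozenset()
    exposure_bias: float = 1.0
    placement_margin: int = 24

    def validate(self) -> None:
        if self.width < 448 or self.height < 448:
            raise ValueError("scene must be at least 448x448 so that a "
                             "224-px grid yields >= 4 tiles")
        probs = np.array([self.cluster_size_distribution.get(k, 0.0)
                          for k in range(1, 9)])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("cluster size probabilities must sum to 1")
        if any(k < 1 or k > 8 for k in self.cluster_size_distribution):
            raise ValueError("cluster sizes must lie in 1..8")
        (a_lo, a_hi), (b_lo, b_hi) = self.animal_axis_px
        if min(a_lo, a_hi, b_lo, b_hi) <= 0:
            raise ValueError("animal axes must be positive")
        if self.background_kind not in BACKGROUND_PRESETS:
            raise ValueError(f"unknown background kind {self.background_kind!r}")
        if not (0.0 <= self.calf_fraction <= 1.0):
            raise ValueError("calf_fraction must lie in [0, 1]")

    @property
    def background_rgb(self) -> tuple[int, int, int]:
        if self.background_mean_rgb is not None:
            return self.background_mean_rgb
        return BACKGROUND_PRESETS[self.background_kind]


@dataclass(frozen=True)
class AnimalRecord:
    """One rendered animal: ellipse geometry plus identity metadata."""

    center: tuple[float, float]          # (row, col)
    axes: tuple[float, float]            # (semi-major, semi-minor) px
    angle: float                         # radians, major axis vs col axis
    calf: bool
    cluster_id: int

    @property
    def area(self) -> float:
        return math.pi * self.axes[0] * self.axes[1]

    def bbox(self) -> tuple[float, float, float, float]:
        """Loose (min_row, min_col, max_row, max_col) of the ellipse."""
        r = self.axes[0]
        cr, cc = self.center
        return (cr - r, cc - r, cr + r, cc + r)

    def translated(self, drow: float, dcol: float) -> "AnimalRecord":
        return replace(self, center=(self.center[0] + drow,
                                     self.center[1] + dcol))


@dataclass(frozen=True)
class DistractorRecord:
    kind: str                            # shed | feeder | tree
    center: tuple[float, float]
    size: tuple[float, float]            # (height, width) of footprint
    angle: float

    def translated(self, drow: float, dcol: float) -> "DistractorRecord":
        return replace(self, center=(self.center[0] + drow,
                                     self.center[1] + dcol))


@dataclass
class SceneTruth:
    """Ground truth for one scene: per-animal geometry and distractors."""

    animals: list[AnimalRecord]
    distractors: list[DistractorRecord] = field(default_factory=list)
    shape: tuple[int, int] = (0, 0)

    @property
    def count(self) -> int:
        return len(self.animals)

    def animal_mask(self, shape: Optional[tuple[int, int]] = None) -> np.ndarray:
        """Boolean union of all animal footprints."""
        shape = shape or self.shape
        mask = np.zeros(shape, dtype=bool)
        for rec in self.animals:
            _paint_ellipse_mask(mask, rec)
        return mask

    def record_mask(self, rec: AnimalRecord,
                    shape: Optional[tuple[int, int]] = None) -> np.ndarray:
        shape = shape or self.shape
        mask = np.zeros(shape, dtype=bool)
        _paint_ellipse_mask(mask, rec)
        return mask

    # -- JSON sidecar ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "count": self.count,
            "animals": [
                {"center": list(a.center), "axes": list(a.axes),
                 "angle": a.angle, "calf": a.calf, "cluster_id": a.cluster_id}
                for a in self.animals],
            "distractors": [
                {"kind": d.kind, "center": list(d.center),
                 "size": list(d.size), "angle": d.angle}
                for d in self.distractors],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneTruth":
        return cls(
            animals=[AnimalRecord(center=tuple(a["center"]),
                                  axes=tuple(a["axes"]), angle=a["angle"],
                                  calf=a["calf"], cluster_id=a["cluster_id"])
                     for a in d["animals"]],
            distractors=[DistractorRecord(kind=x["kind"],
                                          center=tuple(x["center"]),
                                          size=tuple(x["size"]),
                                          angle=x["angle"])
                         for x in d.get("distractors", [])],
            shape=tuple(d["shape"]),
        )


# ---------------------------------------------------------------------
# ellipse geometry helpers
# ---------------------------------------------------------------------

def _ellipse_radius(a: float, b: float, phi: float, theta: float) -> float:
    """Support radius of the ellipse (semi-axes a, b, orientation phi)
    along direction theta."""
    d = theta - phi
    return a * b / math.hypot(b * math.cos(d), a * math.sin(d))


def _ellipse_alpha(rec: AnimalRecord, shape: tuple[int, int],
                   supersample: int = 3):
    """Anti-aliased coverage of the ellipse on its bounding patch.

    Returns (row slice, col slice, alpha array in [0,1], across-axis
    coordinate in [-1,1] for shading).
    """
    a, b = rec.axes
    cr, cc = rec.center
    r0 = max(0, int(math.floor(cr - a - 2)))
    r1 = min(shape[0], int(math.ceil(cr + a + 3)))
    c0 = max(0, int(math.floor(cc - a - 2)))
    c1 = min(shape[1], int(math.ceil(cc + a + 3)))
    if r0 >= r1 or c0 >= c1:
        return None
    s = supersample
    rr = (np.arange(r0 * s, r1 * s) + 0.5) / s - 0.5
    cc_ = (np.arange(c0 * s, c1 * s) + 0.5) / s - 0.5
    dy = rr[:, None] - cr
    dx = cc_[None, :] - cc
    ca, sa = math.cos(rec.angle), math.sin(rec.angle)
    u = (dx * ca + dy * sa) / a          # along major axis
    v = (-dx * sa + dy * ca) / b         # along minor axis
    inside = (u * u + v * v) <= 1.0
    alpha = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    # shading coordinate at pixel resolution
    rrp = np.arange(r0, r1)[:, None] - cr
    ccp = np.arange(c0, c1)[None, :] - cc
    vpix = (-ccp * sa + rrp * ca) / b
    return slice(r0, r1), slice(c0, c1), alpha.astype(np.float32), vpix


def _paint_ellipse_mask(mask: np.ndarray, rec: AnimalRecord) -> None:
    out = _ellipse_alpha(rec, mask.shape)
    if out is None:
        return
    rs, cs, alpha, _ = out
    mask[rs, cs] |= alpha >= 0.5


# ---------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------

def _sample_cluster_sizes(spec: SceneSpec, rng: np.random.Generator) -> list[int]:
    sizes = np.array(sorted(spec.cluster_size_distribution))
    probs = np.array([spec.cluster_size_distribution[s] for s in sizes], float)
    probs = probs / probs.sum()
    out: list[int] = []
    remaining = spec.n_animals
    while remaining > 0:
        k = int(rng.choice(sizes, p=probs))
        k = min(k, remaining)
        out.append(k)
        remaining -= k
    return out


def _place_animals(spec: SceneSpec, rng: np.random.Generator) -> list[AnimalRecord]:
    H, W = spec.height, spec.width
    (a_lo, a_hi), (b_lo, b_hi) = spec.animal_axis_px
    margin = spec.placement_margin
    mean_area = math.pi * (a_lo + a_hi) / 2 * (b_lo + b_hi) / 2
    if spec.n_animals * mean_area > 0.35 * H * W:
        raise CapacityError(
            f"{spec.n_animals} animals of ~{mean_area:.0f} px cannot fit a "
            f"{H}x{W} scene")

    sizes = _sample_cluster_sizes(spec, rng)
    records: list[AnimalRecord] = []
    placed_groups: list[list[AnimalRecord]] = []

    def sample_ellipse(calf: bool, cluster_id: int,
                       center: tuple[float, float]) -> AnimalRecord:
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(b_lo, b_hi)
        if calf:
            a, b = a * 0.5, b * 0.5   # quarter of the adult area
        return AnimalRecord(center=center, axes=(a, b),
                            angle=rng.uniform(0, math.pi),
                            calf=calf, cluster_id=cluster_id)

    def far_from_others(rec: AnimalRecord, group: list[AnimalRecord]) -> bool:
        for other_group in placed_groups:
            if other_group is group:
                continue
            for o in other_group:
                dy = rec.center[0] - o.center[0]
                dx = rec.center[1] - o.center[1]
                gap = math.hypot(dy, dx)
                theta = math.atan2(dy, dx)
                # support radii along the joining direction + clearance
                need = (_ellipse_radius(*o.axes, o.angle, theta)
                        + _ellipse_radius(*rec.axes, rec.angle,
                                          theta + math.pi) + 30)
                if gap < need:
                    return False
        return True

    def in_bounds(rec: AnimalRecord) -> bool:
        a, b = rec.axes
        # exact bbox half-extents of the rotated ellipse
        half_h = math.hypot(a * math.sin(rec.angle), b * math.cos(rec.angle))
        half_w = math.hypot(a * math.cos(rec.angle), b * math.sin(rec.angle))
        cr, cc = rec.center
        return (margin + half_h <= cr <= H - margin - half_h
                and margin + half_w <= cc <= W - margin - half_w)

    for cluster_id, size in enumerate(sizes):
        group: list[AnimalRecord] = []
        for attempt in range(400):
            group = []
            ok = True
            for member in range(size):
                if member == 0:
                    lo = margin + a_hi
                    center = (rng.uniform(lo, max(lo + 1, H - lo)),
                              rng.uniform(lo, max(lo + 1, W - lo)))
                    rec = sample_ellipse(False, cluster_id, center)
                else:
                    base = group[rng.integers(len(group))]
                    theta = rng.uniform(0, 2 * math.pi)
                    rec = sample_ellipse(False, cluster_id, (0.0, 0.0))
                    d = 0.85 * (_ellipse_radius(*base.axes, base.angle, theta)
                                + _ellipse_radius(*rec.axes, rec.angle,
                                                  theta + math.pi))
                    center = (base.center[0] + d * math.sin(theta),
                              base.center[1] + d * math.cos(theta))
                    rec = replace(rec, center=center)
                if not in_bounds(rec) or not far_from_others(rec, group):
                    ok = False
                    break
                group.append(rec)
            if ok:
                break
        else:
            raise CapacityError("could not place all animal clusters; "
                                "reduce n_animals or enlarge the scene")
        # calves nurse beside adults in singles and clusters alike
        for adult in list(group):
            if rng.uniform() < spec.calf_fraction:
                theta = rng.uniform(0, 2 * math.pi)
                calf = sample_ellipse(True, cluster_id, (0.0, 0.0))
                d = 0.85 * (_ellipse_radius(*adult.axes, adult.angle, theta)
                            + _ellipse_radius(*calf.axes, calf.angle,
                                              theta + math.pi))
                center = (adult.center[0] + d * math.sin(theta),
                          adult.center[1] + d * math.cos(theta))
                calf = replace(calf, center=center)
                if in_bounds(calf) and far_from_others(calf, group):
                    group.append(calf)
        placed_groups.append(group)
        records.extend(group)
    return records


def _place_distractors(spec: SceneSpec,
                       rng: np.random.Generator) -> list[DistractorRecord]:
    out = []
    sizes = {"shed": (120.0, 180.0), "feeder": (40.0, 300.0),
             "tree": (160.0, 160.0)}
    H, W = spec.height, spec.width
    for kind in sorted(spec.distractors):
        h, w = sizes[kind]
        center = (rng.uniform(h, H - h), rng.uniform(w, W - w))
        out.append(DistractorRecord(kind=kind, center=center, size=(h, w),
                                    angle=rng.uniform(0, math.pi)))
    return out


def _render_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.height, spec.width
    base = np.array(spec.background_rgb, dtype=np.float32)
    img = np.broadcast_to(base, (H, W, 3)).copy()
    # low-frequency blotches: shared luminance field, green-weighted, so
    # pasture heterogeneity does not flip the channel ordering
    coarse = rng.normal(0.0, 1.0, (H // 64 + 2, W // 64 + 2)).astype(np.float32)
    blotch = ndimage.zoom(coarse, (H / coarse.shape[0], W / coarse.shape[1]),
                          order=3)[:H, :W]
    weights = np.array([10.0, 12.0, 8.0], dtype=np.float32)
    img += blotch[:, :, None] * weights
    return img


_DISTRACTOR_RGB = {"shed": (246, 245, 240), "feeder": (168, 198, 228),
                   "tree": (42, 72, 34)}


def _render_distractor(img: np.ndarray, d: DistractorRecord,
                       rng: np.random.Generator) -> None:
    H, W = img.shape[:2]
    h, w = d.size
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float32)
    dy, dx = rr - d.center[0], cc - d.center[1]
    ca, sa = math.cos(d.angle), math.sin(d.angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    if d.kind == "tree":
        inside = (u / (w / 2)) ** 2 + (v / (h / 2)) ** 2 <= 1.0
    else:
        inside = (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)
    color = np.array(_DISTRACTOR_RGB[d.kind], dtype=np.float32)
    img[inside] = color + rng.normal(0, 2, 3).astype(np.float32)


def generate_scene(spec: SceneSpec, seed: int) -> tuple[RgbImage, SceneTruth]:
    """Render a ground-truthed scene. Deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    img = _render_background(spec, rng)
    distractors = _place_distractors(spec, rng)
    for d in distractors:
        _render_distractor(img, d, rng)
    animals = _place_animals(spec, rng)
    coat = np.array(spec.coat_mean_rgb, dtype=np.float32)
    for rec in animals:
        out = _ellipse_alpha(rec, (spec.height, spec.width))
        if out is None:
            continue
        rs, cs, alpha, vpix = out
        animal_coat = coat + rng.normal(0, 5, 3).astype(np.float32)
        # one flank in shadow: axial gradient across the minor axis
        shade = 1.0 - 0.18 * np.clip((vpix + 1.0) / 2.0, 0.0, 1.0)
        patch = img[rs, cs]
        col = animal_coat[None, None, :] * shade[:, :, None].astype(np.float32)
        img[rs, cs] = patch * (1 - alpha[:, :, None]) + col * alpha[:, :, None]
    img = img * spec.exposure_bias
    img = img + rng.normal(0, spec.noise_sd, img.shape).astype(np.float32)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = SceneTruth(animals=animals, distractors=distractors,
                       shape=(spec.height, spec.width))
    return RgbImage(pixels=pixels, image_id=f"scene_{seed}"), truth


# ---------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SurveySpec:
    """An overlapping strip of frames cropped from one world scene."""

    frame_width: int = 1024
    frame_height: int = 1024
    n_frames: int = 5
    overlap: float = 0.7
    scene: SceneSpec = field(default_factory=SceneSpec)
    frame_interval_s: float = 2.0
    base_latlon: tuple[float, float] = (-21.9744, -47.8497)
    movement_jitter_px: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.overlap <= 0.9):
            raise ParameterError("overlap must lie in [0, 0.9]")
        if self.n_frames < 1:
            raise ParameterError("need at least one frame")
        if self.step < 1:
            raise ParameterError("overlap so high that the frame step is "
                                 "below one pixel")

    @property
    def step(self) -> int:
        return int(round(self.frame_width * (1.0 - self.overlap)))


@dataclass
class SurveyTruth:
    """Frames, per-frame truths, true transforms, and the global registry."""

    frames: list[RgbImage]
    frame_truths: list[SceneTruth]
    translations: list[tuple[float, float]]   # (drow, dcol) frame i -> world
    registry: SceneTruth                      # world-coordinate animals
    overlap_fraction: float

    @property
    def count(self) -> int:
        return self.registry.count


def generate_survey(spec: SurveySpec, seed: int) -> SurveyTruth:
    """Render a survey strip with known overlap and global ground truth."""
    spec.validate()
    step = spec.step
    world_w = spec.frame_width + (spec.n_frames - 1) * step
    world_spec = replace(spec.scene, width=world_w, height=spec.frame_height)
    world_img, world_truth = generate_scene(world_spec, seed)
    rng = np.random.default_rng((seed * 7919 + 17) % (2 ** 31))

    frames, frame_truths, translations = [], [], []
    for i in range(spec.n_frames):
        x0 = i * step
        if spec.movement_jitter_px > 0:
            # animals drift between frames: re-render the strip per frame
            animals = [a.translated(
                float(rng.normal(0, spec.movement_jitter_px)),
                float(rng.normal(0, spec.movement_jitter_px)))
                for a in world_truth.animals]
            pixels = _rerender_with_animals(world_spec, seed, animals)
        else:
            animals = world_truth.animals
            pixels = world_img.pixels
        window = pixels[:, x0:x0 + spec.frame_width]
        visible = [a.translated(0.0, -float(x0)) for a in animals
                   if _bbox_intersects(a, x0, x0 + spec.frame_width)]
        dlat = -0.00001 * i
        frame = RgbImage(
            pixels=np.ascontiguousarray(window),
            timestamp=i * spec.frame_interval_s,
            latitude=spec.base_latlon[0] + dlat,
            longitude=spec.base_latlon[1] + 0.0001 * i,
            altitude_m=30.0,
            image_id=f"frame_{i:03d}",
        )
        frames.append(frame)
        frame_truths.append(SceneTruth(
            animals=visible,
            distractors=[d.translated(0.0, -float(x0))
                         for d in world_truth.distractors],
            shape=(spec.frame_height, spec.frame_width)))
        translations.append((0.0, float(x0)))

    actual_overlap = (spec.frame_width - step) / spec.frame_width
    return SurveyTruth(frames=frames, frame_truths=frame_truths,
                       translations=translations, registry=world_truth,
                       overlap_fraction=actual_overlap)


def _bbox_intersects(rec: AnimalRecord, x0: float, x1: float) -> bool:
    _, c0, _, c1 = rec.bbox()
    return c1 > x0 and c0 < x1


def _rerender_with_animals(world_spec: SceneSpec, seed: int,
                           animals: list[AnimalRecord]) -> np.ndarray:
    """Re-render the world with moved animals (jittered surveys only)."""
    rng = np.random.default_rng(seed)
    img = _render_background(world_spec, rng)
    for d in _place_distractors(world_spec, rng):
        _render_distractor(img, d, rng)
    coat = np.array(world_spec.coat_mean_rgb, dtype=np.float32)
    for rec in animals:
        out = _ellipse_alpha(rec, (world_spec.height, world_spec.width))
        if out is None:
            continue
        rs, cs, alpha, vpix = out
        shade = 1.0 - 0.18 * np.clip((vpix + 1.0) / 2.0, 0.0, 1.0)
        patch = img[rs, cs]
        col = coat[None, None, :] * shade[:, :, None].astype(np.float32)
        img[rs, cs] = patch * (1 - alpha[:, :, None]) + col * alpha[:, :, None]
    img = img * world_spec.exposure_bias
    img = img + rng.normal(0, world_spec.noise_sd, img.shape).astype(np.float32)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------
# on-disk format: PNG frames + JSON sidecars (metadata kept out of EXIF)
# ---------------------------------------------------------------------

def save_scene(img: RgbImage, truth: SceneTruth, outdir: str | Path,
               stem: str = "scene") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img.save(outdir / f"{stem}.png")
    with open(outdir / f"{stem}.truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh)


def save_survey(survey: SurveyTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {}
    for frame, truth, (dr, dc) in zip(survey.frames, survey.frame_truths,
                                      survey.translations):
        frame.save(outdir / f"{frame.image_id}.png")
        meta[frame.image_id] = {
            "timestamp": frame.timestamp,
            "latitude": frame.latitude,
            "longitude": frame.longitude,
            "altitude_m": frame.altitude_m,
            "true_translation": [dr, dc],
        }
        with open(outdir / f"{frame.image_id}.truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh)
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    with open(outdir / "registry.truth.json", "w") as fh:
        json.dump({"overlap_fraction": survey.overlap_fraction,
                   **survey.registry.to_dict()}, fh)


def load_survey_frames(indir: str | Path) -> list[RgbImage]:
    """Load frames of a saved survey, ordered chronologically."""
    indir = Path(indir)
    with open(indir / "metadata.json") as fh:
        meta = json.load(fh)
    frames = []
    for image_id, m in meta.items():
        frame = RgbImage.load(indir / f"{image_id}.png",
                              timestamp=m["timestamp"],
                              latitude=m["latitude"],
                              longitude=m["longitude"],
                              altitude_m=m["altitude_m"])
        frame.image_id = image_id
        frames.append(frame)
    frames.sort(key=lambda f: (f.timestamp, f.image_id))
    return frames
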