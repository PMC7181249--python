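# Methods

This note documents the models, rules and numerical conventions behind
`cattlecount`, the assumptions of its synthetic-scene generator, and the
design choices made where the procedure was genuinely open.

## Problem setting

Nadir UAV frames of pasture at ~1 cm/pixel ground sample distance (GSD),
8-bit RGB, with ~70% frontal and side overlap between consecutive
frames. Animals are light-coated beef cattle (white to light beige);
an adult occupies ~13,000 pixels, a calf about a quarter of that.
Backgrounds range from bright green pasture through pale yellow dry
grass to reddish-brown bare soil, and white-roofed sheds, light-blue
feeders and trees occur as confusable structures. The task is the herd
count over a survey, not per-animal identity or tracking.

## Pipeline

### 1. Region of interest (`roi.py`)

The frame is covered by a regular grid of 224×224-px tiles anchored at
(0,0), row-major, 0-based, half-open windows. Edge tiles are truncated,
not padded: padding would bias any intensity-based classifier, and the
downstream stages only ever see tile content. A tile classifier — a
stateless callable `(tile pixels, window) → label` — marks each tile
`cattle`, `non_cattle` or `unknown`; `unknown` is treated as non-cattle
because only positively identified regions should survive. Non-cattle
tiles are zeroed, giving an `RoiImage` whose `roi_mask` is an exact
union of whole tiles.

The field version of this classifier is a trained CNN, which is outside
this package's scope. Provided implementations of the contract:

* `oracle` — uses scene ground truth. The elliptical truth footprint is
  widened by a margin (default 24 px) before the tile test, because the
  ellipse models the torso only while a detector responds to the whole
  animal (head, legs, tail, shadow — a couple of dozen pixels at this
  GSD). Margin 0 restores the literal footprint-touches-tile rule.
* `brightness` — tile is cattle when ≥ 2% of its pixels lie within a
  per-channel distance of 40 of the nominal coat color.
* `accept` / `reject` — constants, for plumbing tests.
* any dotted path to a `factory(config) → classifier`.

### 2. Color masks (`colorspace.py`)

The ROI is split into four quadrants (top/left take the extra row or
column for odd dimensions) so illumination can be normalized locally.
Per quadrant:

* **Correction factor.** `cf = 85 / mean(Pi)` with the mean taken over
  all three channels of the ROI pixels only — pixels zeroed during ROI
  extraction carry no radiometric information and would deflate the
  mean arbitrarily. An all-zero quadrant has no defined cf and is
  inactive.
* **Channels.** C, M, Y of the CMYK decomposition with standard black
  extraction (`K' = 1 − max(R,G,B)/255`, `C = (1−R/255−K')/(1−K')`,
  etc.), rescaled to [0,255] and rounded; pure black maps to
  C = M = Y = 0. The "custom" channel applies the CIELAB→sRGB formulas
  to the RGB values read as (L, a, b): L = R·100/255, a = G−128,
  b = B−128, D65 white point, sRGB companding, third output channel
  clipped and rescaled to [0,255]. The transform is perceptually
  meaningless but darkens exactly the pixels the coat model expects.
  The scaling maps the 8-bit inputs onto the formulas' natural domains;
  the implementation uses `skimage.color.lab2rgb`, and the tests check
  it against an independent from-first-principles evaluation (±1
  intensity level, the difference between matrix conventions).
* **Content gate.** A quadrant whose Y channel has fewer than 50,000
  nonzero pixels inside the ROI carries too little usable content; it
  is discarded and contributes all-black regions to every mask. Note
  50,000 is just below one full tile (224² = 50,176): the rule
  effectively demands slightly more than a single tile of content.
* **Thresholds.** In all four channels animals are darker than their
  surroundings, so a pixel turns white when its value is strictly below
  the threshold (and inside the ROI). C uses `min(100, 40·cf)`, M uses
  the constant 30 (its role is vetoing reddish soil), custom uses
  `min(150, 120·cf)`. The Y channel uses the histogram-valley rule
  below; the minimum threshold over quadrants with a valid or dark
  status is applied globally — to every kept quadrant — at T, ⌊T/2⌋
  and ⌊T/4⌋, producing three Y masks. Because white means
  below-threshold, these nest: the T/4 mask ⊆ T/2 mask ⊆ T mask.

**Y-threshold rule chain.** A 256-bin histogram of the quadrant's Y
values over ROI pixels (excluding zeroed tiles, which would otherwise
flood bin 0 and fake darkness) is smoothed by a centered moving average
of window 25 with reflected boundaries. Window sums are accumulated in
integer arithmetic so equal-mass windows compare exactly equal — peak
and valley decisions must not depend on float accumulation order. Then:

1. *Dark test*: if the mass of bins 0–9 exceeds the mass of bins
   100–255 (the top 156 bins; bins 10–99 deliberately ignored), the
   quadrant is very dark and the threshold is 10.
2. *Peaks*: strict local maxima of the smoothed curve; plateaus count
   once at their leftmost bin; the endpoint bins cannot be peaks.
3. *Merge*: while two peaks are closer than 30 bins, the smaller is
   dropped (ties keep the lower index).
4. If fewer than two peaks remain the quadrant's threshold is
   discarded; otherwise the two lowest-index peaks p1 < p2 are kept
   (animal and background modes).
5. *Valley*: among bins strictly between p1 and p2 with smoothed
   amplitude below 10% of the second peak's, the one closest to p2 is
   the threshold; if none qualifies, the inter-peak minimum (lowest
   index on ties).

The whole chain is cross-checked for exact agreement against a literal
bin-by-bin reimplementation on 1,000 random histograms spanning dark,
multimodal, spiky and uniform families.

### 3. Fusion and counting (`fusion.py`, `counting.py`)

Each Y mask is ANDed with the M mask, but a Y connected component
(8-connectivity throughout — diagonal-touching animal fragments are one
object) that survives the AND anywhere is restored in full: M acts as an
object-level veto, not a pixel-level one. The result is ORed with the C
and custom masks, giving one final mask per Y variant.

Objects of a final mask are filtered — area < 2000 px removed, area
< 5000 px with solidity < 0.7 removed; "smaller than" is read strictly,
so equality survives — and the elevation factor `ev` is 1.0, 1.25 or
1.5 as the mean retained area falls below 8000, in [8000, 15000), or at
and above 15000 px. `ev` compensates GSD drift over rugged terrain: at
constant flight altitude above the take-off point, higher ground means
larger apparent animals, and the size rules scale with it. With no
objects there is no basis for rescaling and ev = 1.

An object is a candidate cluster when area > ev·15000, or solidity
< 0.65, or (area > ev·12000 and solidity < 0.7). Clusters are thinned
(topology-preserving morphological thinning) for round(20·ev)
iterations — 20, 25, 30 for the three ev values; the rounding is a
choice, the rule gives no decimals — then eroded once with a 3×3 square
element to sever single-pixel necks the thinning cannot remove without
changing topology. Fragments of the result are censused: Ah = number
with area > 100, Sl = number with solidity < 0.5 (a fragment may count
in both), and the object stands for `N = max(1, Ah + Sl − 1)` animals.

Two documented alternatives are config-selectable, because the census
formula cannot be validated against real cluster shapes: an *additive*
mode where the object contributes `1 + max(0, Ah + Sl − 1)`, and a
*strict* empty-object policy where an object completely erased by the
morphology contributes 0 instead of 1 (complete removal is a known
undercount mechanism for isolated animals).

Per final mask the estimate is the sum of per-object counts; the
image's final count is the highest of the three estimates unless it
exceeds the second highest by more than three, in which case the second
highest is taken — a guard against one over-permissive mask shattering
into spurious objects.

On synthetic two-animal clusters the default census systematically
yields N = 1 (the thinning leaves two compact remnants: Ah = 2, Sl = 0,
so Ah+Sl−1 = 1), i.e. a −1 error; the additive mode yields 2. Both
behaviors are pinned by a golden test on a frozen two-ellipse fixture.

### 4. Survey de-duplication (`survey.py`)

Pairwise registration estimates a planar projective transform between
consecutive frames. The primary detector is ORB (500 keypoints,
cross-checked matching, RANSAC projective fit); when it yields fewer
than 6 matched points the fallback is phase cross-correlation
(translation-only), validated by the Pearson correlation of the
overlapped region so that uncorrelated inputs fail loudly instead of
returning nonsense. Synthetic surveys can use their exact generator
transforms (`truth` backend). Consecutive-pair transforms are chained
into frame→world maps (world = first frame's system).

Frames are then processed in chronological order (ties broken by
filename). Per frame:

* Objects whose bounding box comes within the border band (default
  10 px, configurable) of any image edge are removed from the frame's
  count. An entry (world position, count) is stored for later credit
  only if the object is awaiting its first count: centroid inside the
  frame (an object hanging off the edge will be seen whole later and
  counted fresh) and not already in covered territory. Without the
  second condition an animal counted in frame i and border-banded in
  frame i+1's trailing edge would be stored and later credit itself — a
  double count this package's conservation tests caught.
* Objects whose world centroid falls in the union of previously
  processed frame footprints are removed, unless they match a stored
  border entry within the carryover tolerance (default 150 px ≈ 1.5 m;
  the matching radius is undefined in the source procedure). Matching
  is a per-frame greedy assignment by increasing distance, each object
  and each entry used at most once, so a static object always reclaims
  its own (distance-zero) entry before any interloper. A credited
  object is counted with its current count — the interior view is the
  better one — and consumes the entry.

The per-frame adjusted count is raw − border-removed − overlap-removed
+ credited, and the survey total is the sum. On static synthetic
surveys fed ground-truth objects this bookkeeping is exact: the total
equals the world registry size, in either processing direction.

De-dup operates on objects (animals or clusters), so removing a cluster
removes its whole multi-animal count; this mirrors the stated procedure
and is a fidelity limit when clusters regroup between frames.

### Metrics (`metrics.py`)

All metrics are tallied from (estimate, truth) count pairs, not spatial
matches: per pair TP = min(Ce, Ct), FP = max(0, Ce−Ct),
FN = max(0, Ct−Ce); precision = ΣTP/(ΣTP+ΣFP), recall = ΣTP/(ΣTP+ΣFN)
(percent), F1 their harmonic mean. Mean deviation is Σ(Ce−Ct)/N. The
companion spread statistic is the mean absolute deviation Σ|Ce−Ct|/N —
implemented exactly as that formula and named `mean_abs_deviation`,
though survey reports sometimes label this quantity a standard
deviation. Under these definitions precision equals recall whenever the
summed estimates equal the summed truths; the property is asserted on
random inputs. Stratified sub-reports (e.g. by cluster size) and an
actual × estimated confusion matrix are produced on request.

## Synthetic scenes (`scenes.py`)

The generator's job is to produce ground-truthed inputs with the
statistical structure the pipeline assumes — not photorealism, terrain
elevation or a radiometric camera model.

* **Background**: a per-kind base color (green pasture (95,138,68), dry
  pasture (188,178,122), bare soil (150,102,72), mixed) plus
  low-frequency blotches (a coarse Gaussian field upsampled with cubic
  interpolation, green-weighted so channel ordering is preserved) and
  per-pixel Gaussian noise (sd 6 by default).
* **Animals**: anti-aliased filled ellipses (3× supersampling),
  semi-axes drawn uniformly from 80–100 × 42–52 px, giving a mean
  footprint of ~13,300 px ≈ the nominal 13,000-px adult at 1 cm/px;
  coat mean (232,226,212) with small per-animal variation; one flank
  darkened by an axial gradient (up to −18%) to emulate the shadowed
  parts the M channel targets. Calves have half the axes (a quarter of
  the area) and are attached to an adult, touching it, with
  probability `calf_fraction` — reproducing the known failure mode of
  size rules on nursing calves.
* **Clusters**: sizes drawn from a configurable distribution over 1–8
  until the animal budget is reached; each new member is placed against
  a random existing member at 0.85× the contact distance along a random
  direction, so the cluster footprint is a single connected region.
  (All-pairs contact is geometrically impossible beyond three animals;
  connectivity is the operative property.) Distinct groups keep ≥30 px
  clearance; placement is rejection sampling with exact rotated-ellipse
  bounds, and an unsatisfiable request raises a capacity error.
* **Distractors**: white shed (rectangle), light-blue feeder (elongated
  rectangle), dark tree (ellipse), with recorded footprints.
* **Exposure**: a multiplicative bias before sensor noise, for
  under/over-exposure stress tests.
* **Surveys**: one world strip is rendered once and frames are cropped
  from it at step = round(width·(1−overlap)), so ground-truth
  inter-frame transforms are exact and a world registry of animals
  exists by construction; timestamps and synthetic geotags increase
  linearly; metadata goes to a JSON sidecar rather than binary EXIF.
  Movement is off by default; an optional per-frame jitter re-renders
  the strip with perturbed positions for de-dup stress testing.
  Animals keep a 24-px margin from world edges, so nothing is lost off
  the borders of the first and last frames.

What the generator does *not* emulate — and hence what passing tests do
not show about field data: perspective and lens distortion, animal pose
variation (standing/lying, head up/down), partial occlusion by trees,
specular soil reflections, JPEG artifacts, GPS noise, and animal
movement beyond Gaussian jitter. Conclusions from the synthetic suites
are about the correctness of the rules, not about field accuracy.

## Numerical conventions

* 0-based pixel coordinates, half-open windows, row-major order
  everywhere; transforms act on (x, y) = (col, row).
* 8-connectivity for all object and fragment labeling.
* Channel values rounded to integers in [0,255] before thresholding;
  thresholds compared strictly (`value < threshold` ⇒ white).
* Histogram smoothing by integer window sums divided by the window
  length; T/2 and T/4 floored to integer bins.
* Solidity is `regionprops` solidity: area over the pixel count of the
  convex hull computed from pixel coordinates with ±0.5 axis offsets.
  The test oracle reproduces this convention independently with
  shapely.
* Quadrant split: top/left windows take the extra row/column.
* Seeds: every stochastic component takes an explicit integer seed and
  uses `numpy.random.default_rng`; identical (spec, seed) gives
  bit-identical scenes, and identical (config, inputs) gives
  bit-identical CSV/JSON outputs.

## Problem sizes in the test suites

The statistical suites run at desk scale, chosen to keep the object
statistics of the study conditions while fitting a single CPU: recovery
sweeps use 200 isolated-adult scenes (896×896 px, 4 adults each) and
100 two-animal-cluster scenes; mask-nesting is asserted on 100 of those
scenes; de-dup conservation on 100 static 4-frame surveys of 640×640
frames at 70% overlap. Scene dimensions are free parameters of the
generator; the animal-scale parameters (13,000-px adults, quarter-area
calves, 224-px tiles, all Table-style constants) are the study's.

## Known limitations

* The 50,000 active-pixel gate discards quadrants whose cattle region
  is a single tile; an animal wholly inside such a quadrant is lost.
  This is the rule's faithful behavior, visible as the residual ~2.5%
  misses in the isolated-adult recovery sweep.
* The default fragment census undercounts clean two-animal clusters by
  one (see the fusion-and-counting section); the additive mode
  corrects this on synthetic shapes but
  is unvalidated on real ones.
* The C mask degenerates on red-dominant soil (C ≈ 0 everywhere, the
  whole quadrant turns white); the C channel earns its keep only on
  dark images, and counting on bare-soil scenes leans on the area and
  solidity filters.
* De-dup assumes static animals between overlapping frames; movement
  larger than the carryover tolerance breaks the crediting rule, and
  tracking is explicitly out of scope.
* Calves touching adults are frequently absorbed into the adult's
  object and undercounted — the known calf failure mode, reproduced by
  the generator.
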