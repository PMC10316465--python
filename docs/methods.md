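# Methods

`patternpipe` implements an automated photographic re-identification
pipeline for animals with individually distinct coat patterns, together
with a synthetic catalog generator that carries the statistical structure
the pipeline assumes.  This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic experiments do and
do not show.

## The pipeline

Photos flow through seven stages: catalog ingestion or simulation;
detection (boxes per animal); aspect-ratio suitability filtering; a
standing/not-standing classifier; a left/right flank classifier;
background removal; and keypoint-descriptor matching with rank-based
evaluation.  Every stage attributes each removed crop to itself exactly
once, and a manifest records counts, parameters, and seeds so runs are
bit-reproducible.

### Detection and its evaluation

Real deployments use an off-the-shelf animal detector; here an *oracle
detector* reads ground truth from the synthetic catalog and corrupts it at
configured error rates (miss probability per object, Poisson-rate spurious
boxes, uniform corner jitter).  External detectors plug in through a
COCO-style results JSON.  Detections are assigned to ground-truth objects
greedily by descending IoU (threshold 0.5, the standard detection
convention); the test suite checks the greedy matcher against a
brute-force optimal assignment on small instances.

Rates follow photographic-survey reporting conventions: `tp_rate` =
tp/(tp+fp) is the fraction of *emitted* crops containing an animal
(detection precision, despite the name), `fn_rate` = fn/(tp+fn) the
fraction of animals missed, and `fn_rate_suitable` restricts the misses to
crops usable for identification.  Zero denominators flag the rate as
undefined rather than raising.

### Aspect-ratio filtering

A crop's width/height ratio is a cheap proxy for suitability: lying
animals produce wide crops, rotated or occluded flanks narrow ones.  The
operating range is the exact [min, max] of ratios among crops labelled
suitable (canonically [0.65, 2.25]); bounds are inclusive so the defining
crops keep themselves in range.  Suitability ground truth is: at least 80%
of the flank visible, body rotation under ~30°, standing.

### View classifiers

Both binary classifiers share one family: an optional factor-4
average-pooling front end, one to three 3×3 convolutional layers with
16/32/64 filters (each followed by 2×2 max pooling and ReLU), 50% dropout,
flatten, a 64-unit dense layer, and a two-way score layer.  The canonical
configurations are conv [32, 64] at learning rate 1e-5 for pose and
avg-pool + conv [64, 32, 32] at 1e-4 for flank (the flank task is more
prone to overfitting, hence the resolution-reducing front end).
Hyperparameter search samples 20 distinct cells from the 39-cell
depth×filter grid, keeps the best validation accuracy (ties: fewer
parameters, then earlier trial), then sweeps the learning rate over
{1e-3, 1e-4, 1e-5} at the chosen depth.

Because no deep-learning framework is a dependency, the networks run on a
compact numpy engine (im2col convolution, explicit backward passes, Adam).
Choices the architecture family leaves open and how they are fixed here:
optimizer Adam at the spec's learning rate, batch size 32, He
initialization, dense width 64, grayscale 64×64 inputs scaled to [0, 1].
Accuracies are reported with Wilson 95% binomial intervals (a 0.90
accuracy at n = 2,000 gives ~(0.886, 0.912), matching the width of
intervals reported for classifiers of this size in field studies).  Max
pooling splits gradient evenly across tied cells, which matters because
ReLU makes whole blocks zero.

### Background removal

Masks come from ground truth (oracle mode) or a classical estimator:
denoise (σ 1.5), model the background color from the four corner patches
(a tight box around a roughly elliptical animal leaves the corners as the
cleanest samples), threshold the color distance at 0.7×Otsu (Otsu alone
over-segments because the three-tone coat has large internal variance),
then close, fill holes, and keep the largest component.  On sharp,
unoccluded, plain-background crops the estimate overlaps truth at pixel
IoU ≥ 0.8 for ≥ 90% of crops; heavy defocus blur and foreground occluders
are its known failure modes.  A mask whose foreground fraction falls
outside [0.05, 0.95] is judged failed and the crop falls back to its
rectangular state with a flag — emulating how matting occasionally crops
out foreground vegetation instead of the animal.

The default fill is *soft*: background pixels are replaced by a σ-8
low-pass of the scene, which removes background gradients (hence
keypoints) without introducing an artificial silhouette edge.  This
deviates from the more obvious hard black fill, for a measured reason: on
blurred (quality-1) crops a hard edge dominates the SIFT scale space and
contaminates descriptors across a ~40 px torso, making masked crops match
*worse* than unmasked ones.  The hard fill remains available
(`fill="black"`), in which case feature extraction suppresses keypoints
within 5 px of the mask boundary.

### Matching

Features are SIFT keypoints and descriptors (scikit-image implementation,
upsampling 1 for speed at these resolutions), L2-normalized so Euclidean
distance orders like cosine similarity.  Two scorers:

* **Pairwise goodness-of-fit**: nearest-neighbor matches pass a Lowe ratio
  test (0.8) and mutual-best filtering, then a seeded similarity-transform
  RANSAC (1,000 trials, 5 px tolerance); the score is the inlier count,
  zero below 3 inliers.
* **LNBNN** (one-vs-many): all database descriptors are pooled; for each
  query descriptor the k+1 nearest are found (k = 5, a typical small value
  for this family of matchers) and each distinct source crop among the
  first k is credited `max(0, d_{k+1} − d_I)`.  With fewer than k+1 pooled
  descriptors, all are used and the largest distance found serves as the
  background term.  The implementation is checked against an exhaustive
  distance-matrix oracle to 1e-9.

Rankings order by descending score with ties broken by ascending crop id
(determinism for testing).  The query and same-image crops are always
excluded; same-day crops are excluded in evaluation tasks.  Left-flank
crops can be horizontally mirrored and entered as additional identities —
valid because left and right patterns are independent, which the test
suite verifies by checking that a mirrored left crop does *not* match its
own individual's right flank above chance.

### Evaluation

The matching task selects two suitable crops per identity from *different
days* (one query, one database entry, seeded choice).  The cumulative
match characteristic (CMC) reports the proportion of queries whose true
match appears in the top k; the headline number is k = 10 (the number of
candidates an operator will plausibly inspect; accuracy levels off around
there).  Curves are reported to k = 20.  Group contrasts use a 2×2 odds
ratio of matched-within-10 vs not with a Wald CI on the log-OR (Haldane
0.5 when a cell is empty) plus per-group Wilson CIs; per-query tidy CSVs
(rank, group, quality, crop pixels) support fitting richer models —
e.g. a mixed-effects logistic regression — in external tools, which this
package deliberately does not re-implement.  Accuracy is counted per
query (per flank), and each selected pair contributes one query; counting
both directions would double n without adding independent information.

## The synthetic generator

The generator is the package's study system, not a fixture: its defaults
define the conditions under which the pipeline's claims are tested.

**Patterns.**  Each individual's flank pattern is a seeded white-noise
field smoothed at `blotch_scale` (default 6 px) and thresholded at the
`1−frac_white−frac_tan` and `1−frac_white` quantiles into black/tan/white
labels, so realized tone proportions track their targets to within ±0.05.
Left and right flanks are independent draws.  Two built-in regimes encode
a documented population contrast: `zimbabwe_like` (frac_white 0.35,
frac_tan 0.38) has ~7× the white and 1.5× the tan fur of `kenya_like`
(0.05, 0.25); the ratios are the constrained quantities, the absolute
values a modeling choice.

**Rendering.**  A fixed polygonal quadruped (head-right canonical, mirrored
for left-flank views) is textured with the individual's pattern over the
whole body except the dark head, anchored to the torso box — so a
full-body crop carries strictly more pattern than a flank-only rectangle,
as for real patterned canids.  Rotation out of the image plane foreshortens
x by cos θ; lying pose compresses the body and hides most of the flank;
occlusion covers a fraction of the torso with a vegetation-toned block.
Backgrounds are plain (smooth gradient) or cluttered (sharp-edged blobs
and strokes); cluttered scenes are tied to one of `n_sites` (default 6)
camera stations and recur across days, which is exactly the mechanism by
which backgrounds confound matching at fixed camera stations.

**Realism layers** (all seeded per photo): elastic articulation warp with
RMS amplitude drawn U(3, 12) px at correlation length 24 px (body
articulation and perspective — the same animal is never pixel-identical
twice); camera-distance scale U(0.7, 1.15); illumination gain U(0.65,
1.25) and gamma U(0.8, 1.25) plus σ-5 sensor noise; and a three-step
quality ladder mirroring field scoring — score 3 untouched, score 2
Gaussian blur σ 1, score 1 blur σ 3 + 9-px horizontal motion streak +
halved contrast.  The default quality mix is (0.25, 0.40, 0.35), a
camera-trap-like spread.  Under these defaults, top-10 LNBNN accuracy at
89 identities per population sits near 0.97–0.99 (high contrast) vs
0.88–0.92 (low contrast): off the ceiling, separated, and ordered like
the field contrast between high- and low-contrast populations.

**Guarantees.**  Every individual gets at least two suitable right-flank
standing photos on distinct days (photos 3–4 repeat the guarantee for the
left flank when requested), so the two-crop different-day task is always
constructible; remaining photos sample pose, side, rotation, and occlusion
freely.  Catalogs are bit-reproducible from (params, seed); per-individual
pattern seeds derive from CRC-32 of the id so they are stable across runs
and processes.

## What the synthetic experiments show — and don't

Passing tests demonstrate that the pipeline's machinery is correct (exact
oracle equivalences, conservation laws, determinism) and that its
scientific claims hold *in a world with the assumed structure*: persistent
individual patterns, contrast differences between populations, day-varying
photometry and articulation, station-tied backgrounds.  They do not
reproduce accuracy figures from any real catalog: real images add 3-D
articulation, species-level pattern statistics, detector idiosyncrasies,
and matting errors that the generator only sketches.  Absolute synthetic
accuracies are therefore higher than field numbers; the *directions* of
effects (contrast, background removal) are the transferable results.

## Numerical and scale choices

Problem sizes in the test suite are chosen to exercise the documented
conditions on a single CPU: the contrast experiment runs 10 replicates of
89 identities per population; the background-removal comparison 10
replicates of 30 identities; classifier sanity checks use a 2,000/500
split at 64×64 with 10 epochs (pose) and 15 (flank) — enough for the
canonical architectures to exceed 0.90 test accuracy with margin.  The
acceptance script scales the replicate counts to 3 and reports means.
Degenerate inputs are contracts, not surprises: empty descriptor sets
score zero and are flagged; uniform crops yield degenerate masks; rate
denominators of zero flag the rate undefined; a match task whose
individuals all lack distinct-day crops is empty with warnings.

## Known limitations

* The quadruped silhouette is one fixed template per pose; no 3-D model,
  no limb articulation beyond the elastic warp.
* The classical mask estimator assumes a roughly uniform background
  sampled at the crop corners; it degrades on heavy blur and labels
  color-distinct occluders foreground (the same failure mode reported for
  neural matting in the field).
* The numpy CNN engine is sequential-only and CPU-bound; it is adequate
  for the small binary classifiers but not a general training framework.
* LNBNN pools descriptors exhaustively via a k-d tree; million-descriptor
  catalogs would need approximate search, which is out of scope.
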