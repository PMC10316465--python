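# patternpipe

Automated photographic re-identification of individually patterned
animals — the preprocessing and matching pipeline used in photographic
mark–recapture studies of species with unique coat markings (wild dogs,
zebras, giraffes, spotted cats), exercised end to end on a built-in
synthetic coat-pattern generator so its claims can be tested without real
wildlife imagery.

The pipeline: detect and crop animals from photos → discard unsuitable
crops by aspect ratio → keep standing animals (binary CNN) → split left
and right flanks (binary CNN) → remove backgrounds → match flank patterns
with keypoint descriptors → rank candidates and summarize accuracy.

## Who this is for

Ecologists and computer-vision practitioners building or evaluating
re-identification pipelines for camera-trap or survey photography: the
package provides the full preprocessing chain, two matching schemes, the
standard rank-based evaluation, and a seeded synthetic study system for
method development and power analysis at the desk.

## The core methods

**Suitability filtering.**  A crop of width w and height h is kept when
its aspect ratio w/h lies in a range derived as the min/max over crops
labelled suitable (canonically [0.65, 2.25]): lying animals are wider,
rotated or occluded flanks narrower.

**View classifiers.**  Small binary CNNs — one to three 3×3 conv layers
(16/32/64 filters) each with 2×2 max pooling, 50% dropout, dense head;
the flank model adds a factor-4 average-pooling front end.  Architectures
are found by random search over the 39-cell depth×filter grid with a
learning-rate sweep over {1e-3, 1e-4, 1e-5}.

**Matching.**  SIFT keypoints with L2-normalized descriptors, scored
either pairwise (Lowe ratio 0.8 + mutual-best + similarity-RANSAC inlier
count) or one-vs-many with Local Naive Bayes Nearest Neighbor: pooling
all database descriptors, each query descriptor credits each distinct
source crop I among its k nearest with

    score(I) += max(0, d_{k+1} − d_I),

the margin by which I's nearest descriptor beats the background
(k+1-th) neighbor.

**Evaluation.**  Two crops per identity from different days (one query,
one database entry; mirrored left flanks may join as extra identities).
The cumulative match characteristic CMC(k) is the fraction of queries
whose true match ranks in the top k; the headline statistic is CMC(10).
Group comparisons are reported as a 2×2 odds ratio with Wald CI plus
per-group Wilson CIs.

## Worked example

`examples/05_population_comparison.py` simulates two 30-identity
populations that differ in pattern contrast (the high-contrast regime has
~7× the white and 1.5× the tan fur), runs the full match task, and
compares top-10 accuracy:

```
high-contrast: top-10 accuracy 1.00 (30/30 queries), rank-1 0.93
low-contrast: top-10 accuracy 0.97 (29/30 queries), rank-1 0.93
odds ratio (high vs low): 3.10 (95% CI 0.12-79.23)
```

Top-10 accuracy is the proportion of queries whose true match (same
individual, different day) appears among the ten highest-ranked
candidates; the odds ratio > 1 says high-contrast individuals are easier
to re-identify, though at 30 identities per group the interval is wide —
the full-scale experiment below uses 89 per group.

The other examples cover catalog simulation (`01`), detection and aspect
filtering (`02`), classifier training (`03`), pairwise/LNBNN scoring and
ranking (`04`), and the one-config end-to-end run (`06`).  A thin CLI
mirrors the library: `patternpipe simulate | eval-detector |
filter-aspect | train-pose | train-flank | tune | match | run`.

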