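# Methods

This note documents the models, conventions and design choices behind
`morphostrat`, and what the synthetic study conditions do and do not show
about behavior on real slides.

## Cohort definition

Overall survival (OS) is dichotomized with inclusive month cut-offs: short
if OS ≤ 9 months, long if OS ≥ 13 months, with the band in between excluded
to keep indeterminate cases away from the decision boundary. Day-scale
outliers are excluded first and strictly: OS < 15 days (implausible
follow-up) and OS > 1400 days (extreme survivors). Months are converted at
the calendar average 365.25/12 = 30.4375 days/month; the conversion is a
`SurvivalRule` field because month conventions vary across registries.
Rows with missing or negative OS are rejected into a report rather than
labeled.

The retained cohort splits into an 80% experimentation set and a 20%
hold-out, stratified by class (per-class hold-out count = round(0.2·n)).
The experimentation set is dealt round-robin per class into 10
cross-validation folds; in fold iteration *i*, fold *i* is the test
partition, fold *i+1* (cyclic) the validation partition, and the remaining
eight folds the training partition — an 80/10/10 division. At least three
folds are therefore required. All assignments derive from a single seed.

## Tiling

Foreground is segmented on a 16×-downsampled thumbnail (a stand-in for the
second level of a scanner pyramid; plain rasters are downsampled by area
averaging). The HSV saturation channel is thresholded by Otsu's method, with
the data-driven threshold clamped into [0.05, 0.25]: slide background sits
below ~0.1 saturation and stained tissue above ~0.3, so a threshold outside
that band means the thumbnail lacks one of the two classes (a blank slide,
or wall-to-wall tissue) and Otsu would otherwise split the wrong
distribution. A fixed threshold is available in `TilingConfig`.

Slides declared at 20X/40X are resampled to the 10X working magnification by
anti-aliased area averaging (÷2 / ÷4). The patch grid is half-open,
256-pixel stride, row-major; edge tiles narrower than 256 are dropped
(fixed-size encoder input). A tile is kept if its background fraction,
measured against the upsampled foreground mask (single source of truth),
is ≤ 0.6 — strictly more than 60% background is discarded.

## Artifact curation

Rules run in order, and a discarded patch is attributed to the first failing
rule; all three statistics are recorded regardless so thresholds can be
re-examined offline. The aggregate fractions (>60%, >90%, >90%, all strict)
are the method's; the pixel-level cut points are calibrated against the
synthetic generator and exposed in `CurationConfig`:

1. **White/black (RGB).** A pixel is white if every channel ≥ 220 and black
   if every channel ≤ 40; fail if the bad fraction exceeds 0.6.
2. **Glass/debris (HSV).** A pixel is flagged if saturation ≤ 0.10 *and*
   value ≥ 0.82; fail above 0.9. The value cut is deliberately below the
   white-pixel cut expressed in HSV: a bright-but-tinted reflection
   (value ≈ 0.86, min channel ≈ 205) must be catchable by this rule without
   first qualifying as white — requiring value ≥ 0.90 together with
   saturation ≤ 0.10 leaves only a ~12-intensity-unit window below the white
   cut, which sensor/rendering noise straddles.
3. **Pen markings (HED).** RGB is converted to optical density
   (−log10(I/255), floor 1e−6) and unmixed with the Ruifrok H/E/DAB stain
   matrix. The eosin concentration is normalized by a fixed reference
   maximum 0.26 — the 99th percentile of eosin over synthetic tissue
   patches, frozen into the config — and a pixel is flagged when the
   normalized value reaches 0.9. Pen ink projects onto the eosin absorption
   vector at ~4× the tissue reference, so the margin is wide. Whether the
   rule's 90% refers to a pixel fraction or the mean intensity is ambiguous
   in the method description; the fraction semantics (matching rules 1–2) is
   the default and `rule3_semantics="mean"` selects the alternative.

Deconvolution without the non-negativity clip is exposed as
`rgb_to_hed`/`hed_to_rgb` and round-trips within 1 intensity unit for
in-gamut pixels; the clip applies only inside rule 3.

A caveat the synthetic experiments make explicit: under Ruifrok unmixing,
*blue and green* pen inks project negatively on the eosin vector, so an
eosin-threshold rule can only catch inks on the red/magenta side. The
generator therefore renders pen strokes in saturated magenta (a common
slide-marker color); black strokes are caught by rule 1 instead. On real
slides with blue/green markers, rule 3 as printed would pass them — a
limitation of the rule, not of this implementation.

## Encoding

The default encoder is the 16-layer VGG configuration truncated after its
final convolutional block (13 conv layers, channels 64–512, 2×2 max-pool
between blocks), evaluated in float32 as an im2col+GEMM numpy forward pass.
Global average pooling over the last block's 512 maps yields the patch
descriptor; GAP is checked in the tests against a shift-and-add convolution
oracle. Preprocessing is the ImageNet convention (RGB in [0,1], mean
(0.485, 0.456, 0.406), std (0.229, 0.224, 0.225)) and is recorded in
`EncoderSpec`, since silent preprocessing drift is the main reproducibility
hazard with pretrained weights.

Weights are a backend, not core logic: `pretrained_file` loads a
user-supplied `.npz` (no weights are distributed), `random_seeded` draws
He-initialized weights from a seed, and `filter_bank` builds a
deterministic, seed-free cosine filter bank. Random and structured conv
features are standard descriptor baselines; nothing downstream depends on
the weights' provenance. A small `tiny` architecture (3 conv layers, 64-dim
output) keeps desk-scale pipeline runs fast.

## Reduction

Standardization uses the population (ddof = 0) convention; zero-variance
columns map to exactly zero rather than failing, so degenerate synthetic
inputs pass through. PCA uses the sample (n−1) variance convention via a
full SVD; with a retained-variance target the component count is the
smallest n whose cumulative explained-variance ratio reaches the target.
Component signs are fixed by making each component's largest-magnitude
loading positive, so outputs are reproducible across linear-algebra
backends. All statistics are fit on experimentation-set rows only;
validation/hold-out rows are only ever transformed.

## Clustering and K selection

K-means is Lloyd's algorithm with k-means++ seeding, fully determined by an
integer seed: convergence when the maximum centroid shift is < 1e−6 or at
300 iterations; nearest-centroid ties go to the lowest centroid index; an
empty cluster is re-seeded at the point farthest from its nearest centroid.
`n_init` restarts keep the best inertia. The plain Rand index (fraction of
sample pairs on which two partitions agree) is computed from the contingency
table in O(n); silhouette from a single pairwise-distance matrix reused
across the K grid, with singleton clusters scored 0 and a seeded subsample
above a configurable row cap (O(n²) cost).

**Stability.** For each K, the analysis runs `n_permutations` independently
seeded fits and averages the Rand index over consecutive pairs (i, i+1) —
n−1 comparisons, preserving the n-fits budget; all-pairs comparison is a
config option. Each permutation uses the conventional best-of-10 k-means++
restart policy (the sklearn default), so the statistic measures
reproducibility of the *discovered partition* rather than the odds of a
single unlucky initialization. The default permutation count is 1000 in the
pipeline's terms, with 50 used in the desk-scale experiments (the count used
is always recorded).

**Elbow selection.** Silhouette-vs-K curves on well-separated mixtures rise
to the true K and then decline as true clusters get split. The decline is
near-linear — each further K splits one more cluster by a roughly equal
quantum — so "the score drops suddenly" formalized as the maximum forward
difference is tie-prone and lands one to three steps late on equal-mass
mixtures (~55–60% planted-K recovery in our prototyping). The default
`drop_from_peak` method instead returns the **largest K whose score is
within a relative tolerance (10%) of the curve maximum** — the last K before
the score falls suddenly below the best achieved separability. On the same
planted curves this recovers the true K essentially always, and on the
canonical cliff curve (0.9, 0.88, 0.5, 0.48 over K = 2…5) it returns K = 3
as expected. `largest_drop` (maximum forward difference, ties toward smaller
K) remains selectable, and `manual_override` records an explicit K with a
rationale string — on real data the elbow judgment can legitimately be a
human call. Flat or monotonically rising curves return the argmax with a
warning flag.

## Profiles and classification

A slide's profile is the probability distribution of its curated patches
over the K clusters; clusters absent from a slide contribute 0 and slides
with zero curated patches are rejected with a report entry. The decision
tree is grid-searched over depth {2,3,4,5,∞}, min samples per leaf
{1,2,5,10}, min samples to split {2,5,10} and criterion {gini, entropy} —
a small grid spanning under- to over-fitting, since the method names the
axes but not the values. Configurations are scored by mean accuracy on the
per-fold validation partitions; ties break toward shallower trees, then
larger leaves (parsimony). The winner is refit on the full experimentation
set and evaluated once on the hold-out. Sensitivity = TP/(TP+FN) with long
survivors positive; specificity = TN/(TN+FP) is confidence in predicting
short survivors. A `variance_sweep` repeats the reduce→cluster→profile→
classify chain per retained-variance target on a shared split.

## Synthetic study conditions

The generators define the conditions the tests and the acceptance script
measure under:

* **Slides** render background near (248,248,248); tissue as a textured
  pink/purple blend around (195,130,185)/(150,95,165) (saturation ≈
  0.3–0.45, the curation rules' "tissue" side by construction); pen strokes
  in magenta (205,25,185), strongly eosin-projecting; glass reflections as
  bright tinted gray (220,214,204); black lines near (15,15,15). Truth masks
  partition every pixel. Artifact pixel budgets are hit by drawing blobs
  until the budget is consumed, so per-kind area fractions track the spec
  closely; `shapes_per_artifact=1` concentrates a kind into one compact blob
  so that entire 256×256 working-resolution tiles are pure artifact —
  required for measuring artifact-tile discard rates (a 10% pen budget
  scattered in thin strokes contains no fully-pen tile). Curation fidelity
  runs on two 4096² slides (60% tissue, 8% pen, 8% glass, 7% blank) with
  tile purity ≥ 0.99 measured on the base-resolution truth masks, within a
  single kind: each rule targets one artifact class, and a tile straddling
  two kinds (say 75% pen, 25% glass) structurally evades every per-class
  threshold — a property of the three-rule design worth knowing on real
  slides, where adjacent artifacts do co-occur.
* **Feature cohorts** draw patches from k isotropic unit-variance Gaussians
  whose centers are mutually equidistant at `separation` × the
  per-direction within-cluster std, rotated into general position (random
  orthonormal frame). The rotation matters: axis-aligned centers are
  pathological under standardize→PCA, because per-column unit-variance
  scaling exactly whitens single-coordinate signal. Per-patient mixing
  weights come from a symmetric Dirichlet (concentration 1 by default;
  small values emulate slides dominated by one morphology) or an explicit
  simplex matrix. K-recovery experiments use 20 patients × 100 patches
  (2000 patches), separation 8, feature dim 512, reduced to 10 principal
  components — the smallest PC setting of the method's own sensitivity
  sweep, where the silhouette elbow is sharpest.
* **Profile cohorts** draw class-conditional Dirichlet profiles; the default
  contrast is 5:1 in two coordinates of a K = 7 simplex (short ~
  Dir(5,1,…,1), long ~ Dir(1,5,1,…,1)), balanced classes. The no-signal
  control uses identical concentrations for both classes.
* **Clinical tables** draw OS from uniform/lognormal/exponential/point
  distributions, defaulting to uniform on [0, 1600] days so that every
  labeling band is populated.

What passing these conditions shows: the pipeline's statistics, selection
machinery, leakage discipline and curation rules behave correctly when their
assumptions hold and the planted effects are strong. What it does not show:
performance on real histology — encoder features of real tissue are not
isotropic Gaussians, real artifact palettes are broader than the rendered
ones (blue/green pens in particular), and real prognostic signal is far
weaker than the planted Dirichlet contrast. Numbers from the synthetic
conditions are recoverability checks, not clinical performance claims.

## Numerical conventions and degenerate inputs

Seeds: one master seed derives per-stage seeds by fixed offsets; all derived
seeds stay below 2³¹. Optical-density floor 1e−6; standardizer tolerance
checks |mean| < 1e−8 and |var−1| < 1e−6 on training rows; PCA ratios match a
brute-force eigensolver to 1e−8 on small instances; silhouette matches a
double-loop oracle to 1e−10. Empty patch lists, constant columns, rank-1
data, single-cluster silhouettes, empty evaluation sets, and classes smaller
than the fold count all either pass through as defined above or fail with a
named error — never silently.

## Known limitations

* The eosin-based pen rule cannot flag blue/green inks (negative eosin
  projection); see the curation section.
* No pyramid-aware WSI backend is wired in: slides are plain rasters with a
  declared magnification tag. The `SlideHandle` seam is where an
  OpenSlide-style reader would attach.
* The encoder forward pass is CPU numpy; at ~2 s per 256×256 patch through
  the full 512-channel stack it is meant for validation and small cohorts,
  not production-scale encoding. The `tiny` architecture or a user-supplied
  accelerated encoder behind the same `FeatureMatrix` contract covers larger
  runs.
* Desk-scale experiment sizes (2000-patch cohorts, 50 permutations, two
  4096² slides, 20 classifier seeds) were chosen so the whole validation
  suite runs in minutes on one CPU; they are stated alongside every reported
  quantity.
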