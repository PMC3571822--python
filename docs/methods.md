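# Methods

## Model

The classifier is a supervised minimum-distance rule in RGB colour space.
Each class *k* is summarized by the channel means μₖ = (R̄, Ḡ, B̄) and the
3×3 sample covariance Sₖ of its reference pixels (denominator *n* − 1,
channel order fixed as R, G, B). A pixel **x** is assigned to
argminₖ d(x, k) with d(x, k) = √((x − μₖ)ᵀ Sₖ⁻¹ (x − μₖ)). This is a
distance rule, not quadratic discriminant analysis: there is no
log-determinant term and no prior, so a class with a larger fitted
covariance volume attracts boundary pixels. That choice follows the
method being implemented; its consequences are quantified below.

Ties are broken toward the lowest class index. The assignment is
deterministic and, on small instances, is verified exactly against a naive
per-pixel loop.

### Covariance source

The defining equations can be read as estimating one covariance "in the
given image" or one per class. The default is **per-class** covariance from
each class's reference pixels — the only reading under which seven classes
with different spreads are separable. A `covariance="pooled_image"` mode
estimates a single covariance from the image under analysis and uses it
for every class, honouring the literal single-image reading. Similarly the
class representative is the **centroid** by default, with
`representative="nearest_reference"` (minimum over the individual
reference pixels) available; the centroid is the conventional estimator
and O(1) per class per pixel.

### Regularization

40 hand-picked pixels from a near-uniform region often give a
rank-deficient S. S is therefore shrunk: (1 − λ)S + λ(tr S/3)I with
λ = 0.1 by default (λ ∈ [0, 1]; λ = 0 leaves S untouched, λ = 1 is a
scaled identity). A sample with literally zero variance maps to 10⁻⁶·I.
The inverse is checked against S to 10⁻⁸ after fitting.

## Grape cleanup

Order of operations on the binary Grape mask: morphological opening
(removes small misclassified pixel groups), closing + flood fill of
enclosed background (repairs the bright bloom speckles inside clusters),
removal of 8-connected components below a size threshold, and a lower-half
constraint keeping rows ≥ ceil(H·(1 − f)).

Numerical and structural choices:

* Structuring element 3×3 square, one opening and one closing pass,
  minimum component 25 px — chosen for the speckle scale at 800×600, all
  configurable (`MorphParams`).
* Foreground connectivity is 8-neighbour everywhere; hole filling floods
  the 4-connected background, the complement-dual convention.
* The published description of the spatial rule ("positions 400 to 800" of
  the vertical axis on an 800×600 frame) is internally inconsistent, so it
  is implemented as a resolution-independent fraction of image height,
  default one half.
* The closing stage runs on a padded copy so border-touching blobs are
  never eroded (extensivity holds exactly: input ⊆ output).
* A single pass of the sequence is **not** idempotent in general — closing
  can create structures a subsequent opening removes — so the cleanup
  iterates the sequence to a fixed point. Convergence takes ≤ 3 passes on
  adversarial random masks (no cycles observed in 200 trials) and 1 pass
  on realistic cluster blobs; a safety cap of 16 passes applies.
* Pixels removed from Grape are relabeled to their second-smallest-distance
  class (this needs the distance stack from classification), and pixels
  added by hole filling become Grape, so the label image stays complete
  and total counts are conserved.

## Calibration

Per-image pixel counts (leaf grades added together for the leaf predictor;
the single Grape class for yield) are regressed on the ground-truth
measurements by ordinary least squares. Records are split 2/3 train / 1/3
validation at random with a seed (`round(n·fraction)` training records;
optional stratification by defoliation stage). Validation reports:

* **R²** — headline convention is the squared Pearson correlation between
  predicted and observed values; the 1 − SSE/SST form is also reported
  (`r2_one_to_one`), and they differ exactly when predictions are biased.
* **RMSE** in the target's units (m² or kg).
* Constant observed values make R² undefined; this is flagged rather than
  silently returning a number, and RMSE is still computed.

Published calibration coefficients are never used inside the pipeline:
the slope of such a line is specific to the camera geometry and the
(unknown) predictor scaling of the dataset it was fitted on.

## The synthetic scene generator

`synthimage` emulates the acquisition layout the method was designed for:
a white screen behind the vine (background ≈ (235, 235, 235)), a
trunk/cordon/shoot wood skeleton, dark bluish grape ellipses confined to
the lower half of the frame, and disk-shaped leaf blobs in four grades of
green. Default palette (mean RGB, per-channel sd 12, independent Gaussians
clipped to [0, 255]):

| class | mean RGB |
|---|---|
| Background | 235, 235, 235 |
| Wood | 105, 75, 45 |
| Grape | 50, 45, 75 |
| Old leaves grade 1 | 55, 105, 45 |
| Old leaves grade 2 | 80, 120, 40 |
| Young leaves grade 1 | 95, 155, 70 |
| Young leaves grade 2 | 120, 170, 90 |

Scenes are 800×600 by default. Truth labels are recorded while painting,
and the physical truths are exact linear images of the truth counts:
leaf area = 2×10⁻⁵ m²/px × leaf pixels, yield = 10⁻⁴ kg/px × grape
pixels. The seven-stage series removes leaf blobs in thirds at steps 1, 3
and 5 (complete defoliation at 5) and thins clusters by every third at
step 2, every second remaining at step 4, and all at step 6.

By default leaves are placed clear of every grape cluster, so cluster
thinning never changes the visible leaf area and leaf counts are strictly
non-increasing over the series; an `occlusion=True` mode paints leaves
over grapes to emulate dense canopies, where grape visibility (and hence
yield estimation) degrades qualitatively.

**What the generator does not emulate** — and what passing tests therefore
do not show about field images: illumination gradients and shadows,
specular highlights and the within-cluster bloom gradient, leaf texture
and veination, perspective and camera distortion, anisotropic
(full-covariance) class colour distributions (available as an option but
not the default), and multi-layer leaf occlusion. Recall figures on the
synthetic cohort (≈99%) are accordingly optimistic relative to the ~92–98%
achievable on real field images; the synthetic cohort is a correctness and
regression harness, not a field-performance claim.

### Record-level calibration cohorts

The calibration benchmarks do not need rendered images: they simulate
(count, measurement) records directly. Per-vine baselines are uniform on
[1, 6] m² (leaf) or [1, 5] kg (yield); stage factors are (1, 2/3, 1/3)
across I0/I2/I4 (leaf) and I1/I3/I5 (yield), matching the thinning
arithmetic of the series; counts are exact linear images of the truth and
measurements add Gaussian noise (sd 0.3 in target units). Cohort size is
10 vines × 3 stages = 30 records, split 20/10.

## Known limitations

* Adjacent leaf grades in the default palette sit ~2.5–3 sd apart, so even
  the optimal rule confuses ~7–11% of their pixels in each direction.
  Aggregated over the grades these flows cancel (cohort leaf totals
  recover within ~0.2%), but **individual-grade** counts carry systematic
  net errors of several percent when covariances are estimated from 40
  reference pixels, because the fitted covariance volumes bias the
  minimum-distance competition (verified: with 5 000 reference pixels per
  class the per-grade recovery error drops to ≤ ~2%). Per-grade counts
  should therefore be read as indicative; the functional outputs (leaf
  total, grape total) are accurate.
* The classifier is per-pixel colour only — no texture or spatial
  features — so classes that overlap in colour space (fungicide-tinted
  leaves vs grapes, sky vs grapes) are only separable via the spatial
  cleanup stage.
* The lower-half constraint assumes fruit in the lower half of the frame;
  other training systems need a different `fraction`.
* Calibration lines are camera- and scene-geometry-specific and do not
  transfer between setups.

## Problem sizes

The shipped benchmarks use 10 scenes of 800×600 with 7 classes
(classification cohort) and 30-record calibration cohorts; both complete
in seconds to a few minutes on a single CPU, and all randomness is seeded.
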