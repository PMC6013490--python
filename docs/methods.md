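# Methods

This note documents the models and procedures implemented in `bbsynth`,
the defaults that matter, the numerical choices made where the design was
genuinely open, and the limits of what phantom experiments can show.

## 1. Digital phantoms (`bbsynth.phantom`)

**What they emulate.** One phantom is an ellipsoidal brain (axes ≈ 0.40,
0.40, 0.38 of the grid) with a white-matter core, a grey-matter shell
(outer 12 % of the ellipsoidal radius), an optional detached bright
skull/scalp rim, three caliber classes of tubular vessels, and spherical
blob metastases. Two co-registered volumes are rendered from one label
map:

* *GRE-like*: vessels (0.95) and lesions (0.80) bright against WM (0.50)
  and GM (0.35); background 0.05.
* *BB-like*: vessel voxels at background level (0.05), lesions retained
  (0.80), reduced WM/GM contrast (0.50/0.40), a mild Gaussian blur
  (σ = 0.5 voxel by default) emulating the lower image quality of the
  long fast-spin-echo acquisition, and optionally a fraction of vessel
  voxels restored to GRE brightness *after* the blur (flow artifacts are
  sharp) to emulate imperfect flow suppression.

Independent Gaussian noise (σ = 0.02 by default) is added to both volumes
and clipped to [0, 1]. All randomness derives from a single integer seed;
a fixed seed gives bit-identical truth and volumes.

**Vessel geometry.** Type 1 (radius 3 mm): a dome-shaped midline trunk
(dural-sinus analogue) plus midline branches hanging off it. Type 2
(radius 2 mm): lateral branches leaving the trunk on alternating sides.
Type 3 (radius 1 mm): short arcs at ≈ 0.8 of the brain radius, pushed
away from the midline and deliberately *not* connected to the trunk —
small cortical branches whose connectivity to main vessels is not evident
is precisely the situation that defeats connectivity-based vessel
segmentation and motivates the two-pass extraction.

**Lesions.** Spheres with radius drawn uniformly from 0.75–5.5 mm
(maximum axial diameter 1.5–11 mm), matching a caseload dominated by
small metastases with a minority under 2 mm. Placement enforces: fully
inside the brain, ≥ 3 voxels clear of any vessel (so that lesion truth
and vessel truth never touch), and non-overlapping; bounded retries, then
a placement error.

**What they do not model.** Anatomy, partial-volume effects at object
boundaries (objects are binary-rasterized), pulse-sequence physics,
motion, bias fields, or lesion texture. Consequences: intensity classes
are cleanly separated, so clustering/growing thresholds that pass here
have headroom that real data would consume; conversely the absence of
partial volume makes *small* objects harder for the CNN than their
real-world counterparts (a 1-voxel-radius tube is all-or-nothing).

## 2. Pre-processing (`bbsynth.preprocess`)

* **Normalization** divides by the volume maximum (max maps to 1
  exactly; idempotent and monotone). A robust upper-percentile mode
  (off by default) exists for noisy real data, where a single hot voxel
  would otherwise set the scale.
* **Registration** is rigid (6 DOF), multi-resolution (shrink 4/2/1),
  with a normalized cross-correlation metric and regular-step gradient
  descent, via SimpleITK. Same-session brain MRI needs no deformable
  component. Normalization precedes registration; the NCC metric is
  intensity-scale invariant, so the order does not affect the optimum.
  If the optimization fails or does not improve the metric, the
  best-effort (initializer) transform is returned flagged
  `converged=False`.
* **Brain extraction** is Otsu thresholding, morphological closing
  (ball radius 2), largest 26-connected component, then hole filling
  *within that component* (filling before component selection would
  merge a closed skull shell with everything inside it). This replaces
  anatomy-specific tooling, which has nothing to key on in a phantom.

## 3. Auto-labelling (`bbsynth.autolabel`)

Pipeline: fuzzy c-means → region growing → fill/blend → difference-image
thresholding → fill/blend. Parameters live in `AutoLabelParams`; the
procedure leaves several details open, and this implementation fixes them
as follows:

* **FCM**: 3 clusters over brain voxels (dark/mid/bright), fuzziness
  m = 2, tolerance 1e-5 on the centroid shift, ≤ 200 iterations,
  centroids initialized at fixed intensity quantiles — deterministic, no
  random initialization. The brightest cluster is the vessel candidate
  class. Defuzzification ties resolve to the lower cluster index.
* **Region growing seeds**: candidate voxels at or above the 99.5th
  intensity percentile of the candidate class *and* above an absolute
  floor of 0.7 (normalized units). The floor is what makes the
  vessel-free case degrade gracefully: without it, the brightest noise
  tail of normal parenchyma would always seed growth. Growth accepts
  26-connected candidate voxels within `grow_tol = 0.1` of the
  seed-region mean; this is implemented as connected components of the
  eligible set restricted to seeded components, which is equivalent to
  breadth-first growth under a fixed acceptance rule and independent of
  visiting order.
* **Fill and blend**: vessel-mask voxels take the paired BB values
  exactly; a one-voxel 26-neighborhood dilation ring takes
  0.5·BB + 0.5·base to avoid a discrete intensity step at the mask edge.
  A linear distance taper across wider rings is available but off by
  default. The second fill blends the *intermediate* image (not the
  original GRE) in its ring.
* **Pass 2**: the difference (intermediate − BB) is thresholded at
  τ = 0.25 within the brain mask eroded by 2 voxels. Non-vessel tissue
  has near-zero difference (pass-1 vessels were already replaced, other
  tissues are similar in both volumes), so surviving vessels stand out;
  on phantoms any τ in roughly [0.2, 0.5] selects the same voxels — a
  `threshold_sweep` utility exposes that stability curve. The erosion
  excludes brain-surface partial-volume voxels, where BB blur produces
  small positive differences that are not vessels; true cortical
  vessels sit deeper than the 2-voxel rim. Thresholding operates on the
  raw difference; optional smoothing is available but off by default.

On default phantoms the two passes jointly cover every true vessel voxel
and no lesion voxels, and voxels outside the masks and rings equal the
GRE input bit-exactly (lesion preservation by construction).

## 4. Residual 3D CNN (`bbsynth.bbnet`)

**Architecture.** N 3×3×3 convolution layers; layers 1..N−1 carry W
feature maps each followed by batch normalization and ReLU; the final
layer has one map and no normalization/activation; the input is added
elementwise to the final output. Every convolution zero-pads by one voxel
on all six faces, so any input shape is preserved (a 2D reading of the
padding would break the through-plane axis; the isotropic choice is the
only one consistent with shape preservation of a 3D kernel). With a zero
final layer the network is exactly the identity — the residual
formulation makes "change nothing" the natural starting point for a
mapping that is mostly the identity apart from vessels.

The reference architecture is N = 25, W = 64. It is constructed and
unit-tested but not trained here; the *desk-scale* configuration
(N = 5, W = 16, `NetworkConfig.desk_scale()`) is what the test suite
trains. Desk-scale also initializes the final convolution at zero (the
zero-residual-branch trick): batch norm forces unit-variance input into
the final layer, so a variance-scaled random final layer would start the
network far from the identity and waste a large share of a short run
undoing that.

**Optimization.** MSE loss; Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — the
conventional constants); per-step gradient clipping by *global* L2 norm
at 1; learning rate divided by 10 every 10 epochs from 1e-5; batch
size 10; MSRA (He) weight init; 31³ co-located input/label patches;
30-epoch cap with early stopping when the validation loss has not
improved for 5 epochs; fine-tuning restarts at 1/10 the initial rate
with a 60-epoch cap. Patch origins are seeded-uniform with a
configurable minimum fraction of patches forced to contain foreground
(vessel or lesion) voxels when truth is available — with ~2 % foreground
occupancy, unconstrained sampling would starve the loss of the voxels
that matter.

The desk-scale training configuration (`TrainConfig.desk_scale()`)
raises the learning rate to 1e-3: at ~1e-5 a few hundred Adam steps
cannot move the weights appreciably; the full-scale schedule belongs to
a regime of ~10⁵ steps. The end-to-end test trains on 400 patches of
15³ from 4 phantoms for 30 epochs (1200 steps, minutes on one CPU) at a
constant rate, with patch sampling balanced between vessel-centered,
lesion-centered and unconstrained origins. The balance matters: vessels
contribute several times more voxels than lesions, and an unbalanced
MSE first finds the "suppress every bright blob" solution — vessels
dark, lesions erased; the lesion-centered half of the foreground quota
supplies the gradient that teaches the network to put lesions back.
The smaller patch raises the foreground share per patch and cuts the
per-step cost, buying the longer horizon that shape discrimination
needs. Problem sizes were chosen as the smallest at which the held-out
behavior (suppression ordering, lesion sensitivity) is stable.

**Inference.** Whole-volume forward pass in evaluation mode (batch norm
uses accumulated running statistics — the training-mode alternative
would make the output depend on the tiling of the input). Oversized
volumes fall back to overlapping tiles with one receptive-field margin
discarded before stitching; away from the volume boundary this equals
the whole-volume result exactly. Outputs are clamped to the valid
normalized range [0, 1]; an untrained or aggressive network can
overshoot below zero at vessels, which has no physical meaning and
would break downstream ratio statistics.

## 5. Evaluation (`bbsynth.evalmetrics`)

* **R_s** = SI_WM / (0.5·(SI_WM + SI_vessel)) per vessel caliber class;
  SI_vessel is the mean of the three vessel-ROI means of the class (not
  the pooled voxel mean — three small ROIs weigh equally regardless of
  size). The phantom ROI scheme mirrors the nine-ROI manual placement:
  three spherical ROIs per class centered at centerline midpoints of the
  first three segments, restricted to true vessel voxels of the class;
  the WM ROI is a radius-3 ball at the deepest point of vessel- and
  lesion-free WM (deterministic).
* **Lesion detection** replaces human conspicuity scoring with an
  objective call rule: 26-connected components above `call_threshold`
  (default 0.65, the midpoint between the phantom WM and lesion levels)
  inside the brain, outside the dilated true-vessel set, of ≥ 2 voxels.
  A call hits a lesion when its centroid lies within the lesion sphere;
  each lesion is matched at most once (largest calls first); unmatched
  calls are false positives. Sensitivity is reported per lesion, overall
  and for the ≥ 2 mm maximum-axial-diameter subgroup, and per volume
  ("per patient": a lesion-bearing volume counts as detected with ≥ 1
  hit; any volume with ≥ 1 spurious call counts once as a false-positive
  volume). Free-response ROC summary statistics (figure-of-merit
  analyses) are out of scope; the TP/FN/FP tallies are the raw material
  such analyses consume.
* **Weighted kappa** for two raters on the 3-point ordinal scale, via
  `statsmodels` (linear weights by default, quadratic optional; the
  weighting scheme is a reporting choice, and linear is the conservative
  default for a 3-level scale). If both raters use a single category
  throughout, chance agreement is 1 and kappa is undefined — returned as
  NaN with a warning rather than a crash.

## 6. Known limitations

* Phantom intensity classes are well separated; the auto-labelling
  thresholds (`seed_min_intensity`, τ) are stable across wide ranges
  here but would need the provided sweep utility on real data.
* The desk-scale CNN attenuates the smallest lesions more than large
  ones (they are locally indistinguishable from cortical vessel dots —
  the same failure mode reported for full-scale training, exaggerated by
  the reduced capacity and horizon). The ≥ 2 mm subgroup is the honest
  evaluation target at this scale.
* The NumPy network is single-threaded BLAS-bound; it exists to make the
  pipeline self-contained and testable, not to compete with GPU
  frameworks. The full-size 25-layer network is constructible and passes
  its structural tests but is not trained in the suite.
* Registration is validated on synthetic rigid displacements only.
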