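# Methods

This note documents the models, conventions and numerical choices behind
`rfmap`, and what the synthetic phantoms do and do not establish.

## Gray-level quantization

All texture matrices operate on integer gray levels. The default is
equal-width binning into 16 levels over the **whole patch's** intensity range
("global" policy), computed once before the kernel slides; this makes
per-pixel map values comparable across positions, which the cohort-level map
correlations rely on. A per-window policy is available. A constant input
collapses to a single level. Explicit range endpoints can be supplied, which
makes the features exactly invariant to intensity shifts applied consistently
to data and endpoints.

## The texture bank

75 features over five families, in a fixed canonical order (GLCM 24, GLDM
14, GLRLM 16, GLSZM 16, NGTDM 5), following the IBSI-conformant formula
conventions:

* **GLCM** — distance 1, four 2D directions (0°, 45°, 90°, 135°), symmetric
  accumulation, each direction normalized *then* averaged. Level values (not
  dense indices) enter the formulas; `Ng` in Idmn/Idn is the number of
  distinct levels present in the window. Imc1/Imc2 use base-2 logs; MCC is
  the square root of the second-largest eigenvalue of the transition matrix.
* **GLRLM** — maximal equal-level runs along the same four directions,
  counts summed; RunPercentage divides by (pixels × directions).
* **GLSZM** — 8-connected zones by default (4-connectivity available);
  zone sizes always partition the window's pixel count.
* **GLDM** — dependence = number of neighbours within Chebyshev distance 1
  whose level differs by at most α = 0; the matrix column index is
  dependence + 1, and that shifted index is the "size" in the emphasis
  formulas. Note that on a two-level checkerboard the *diagonal* neighbours
  share the centre's level, so dependences are not zero there.
* **NGTDM** — per-level summed absolute deviation from the in-window
  neighbourhood mean (Chebyshev distance 1).

**Degenerate-window conventions** (all tested): on a constant window,
entropy-, variance-, contrast-type features are 0; uniformity-,
maximum-probability- and inverse-difference-type features are 1; GLCM
Correlation is defined as 1 and MCC as 1; NGTDM Coarseness is capped at
`1e6` (the cap also applies whenever the weighted deviation sum underflows
to 0); Busyness, Complexity and Strength fall back to 0 when their
denominators vanish. Every feature value is finite on every input.

The implementation is validated feature-by-feature against a naive,
loop-based reimplementation of each formula (independent code path) to 1e-9
relative tolerance on random windows.

## Sliding-map construction

A k × k kernel (default 7) centres on each pixel; the window's feature value
fills that pixel, giving maps with the patch's dimensions. Borders are
handled by reflect padding by default (`edge` and `none` — with an explicit
valid-region mask — are available). Maps are computed on the
native-resolution patch and only then resized to 224 × 224 (bilinear);
computing texture after interpolation would smear the very statistics the
kernel measures. Correctness is defined by the per-pixel window-extraction
oracle: every map value must equal `features_75` of the manually extracted
window, exactly.

## Patches and composites

Coordinates are 0-based, half-open throughout. The expanded patch grows the
ROI bounding box by 10 px per side (clipped at image borders, recorded in
provenance). Network inputs are 3 × 224 × 224 with per-channel min-max
normalization to [0, 1] (constant channels map to 0; z-score is available):
either the grayscale patch broadcast three times (pilot) or
(gray, RFM-A, RFM-B) (boosted).

## Redundancy pruning

Per-subject Pearson correlation between flattened maps (all patch pixels;
zero-variance maps get r = 0 and a flag), averaged elementwise over training
subjects. Pruning is greedy on |r|: while any retained pair exceeds the
threshold (default 0.95), the member of the worst pair with the larger mean
absolute correlation to the other retained features is dropped; ties drop
the feature later in canonical order. Absolute r is used because
anti-correlated maps are equally redundant. The procedure is deterministic
and idempotent, and the retained set provably contains no pair above the
threshold.

## Classifier

The architecture contract is transfer-learning-shaped: a **frozen
convolutional base** and **two trainable FC layers** with dropout between
them and a softmax output. The desk-scale default base ("tiny") is a
two-block CNN with fixed He-scaled Gaussian filters drawn once from a fixed
seed; alternative bases plug in via a two-method protocol
(`features`, `backward_features`).

Design choices in the tiny base, each of which matters for the saliency
stage:

* the input is average-pooled 224 → 28 before the first convolution, so the
  base behaves like a generic coarse feature extractor rather than a
  texture microscope;
* convolutions use symmetric padding with an exact adjoint in the backward
  pass — zero padding would make the artificial border-contrast ring the
  strongest activation and dominate every saliency map;
* the pooled features are the per-filter response *energies* (spatial mean
  of the squared ReLU activations, 8 + 16 = 24 values). With second moments
  only, the class-score gradient at a pixel is proportional to the local
  activation magnitude, so saliency maps inherit the activations' spatial
  localization;
* feature standardization floors each sd at 5% of the feature's absolute
  mean, preventing near-constant (uninformative) features from dominating
  the input gradient through the 1/sd factor.

The head (features → 24 hidden ReLU units → dropout 0.25 → 2-way softmax) is
trained by mini-batch Adam (lr 0.01, batch 16, 200 epochs, weight decay
1e-4), deterministically for a given seed. Because the base is frozen, base
features are computed once per image and the repeated-training protocol
re-trains only the head, which keeps 50-run ensembles cheap.

**Stability protocol**: R runs from consecutive seeds; the reported model is
the run whose validation AUC is closest to the ensemble mean (ties → lowest
seed); its per-subject probabilities feed fusion. The reference protocol
uses R = 50; phantom experiments here use R = 10, which is enough to
stabilize the ensemble mean at the phantom's effect size.

**Saliency** is the vanilla input gradient of the positive-class logit,
reduced over channels by the maximum absolute value and max-normalized
(skipped and flagged when identically zero). Gradients are exact — verified
against finite differences — because the whole model is differentiable in
closed form.

## Map selection

Retained maps are resized to the saliency map's dimensions and correlated
per subject; ranking is by the mean (signed, by default) Pearson r over
training subjects, and the top two are selected. Signed r matches the
selection rule's definition; an absolute-value mode is available.

## Fusion and evaluation

Fusion is a maximum-likelihood logistic regression (intercept + one
coefficient per branch probability stream), via `statsmodels`; perfect
separation is detected (non-finite or exploding coefficients) and triggers a
flagged fall-back to an L2-penalized fit. The decision threshold is Youden's
J on the training ROC, frozen for validation cohorts.

* **AUC** is the Mann–Whitney statistic (ties count ½), equal by
  construction to brute-force concordant-pair counting; its CI comes from
  the DeLong placement-value variance, clipped to [0, 1].
* **DeLong test** — two-sided paired comparison of correlated AUCs from the
  placement-value covariance; a model compared with itself returns z = 0,
  p = 1 exactly.
* **IDI** — difference of discrimination slopes, with the asymptotic z-test
  from the within-class variances of the paired probability differences.
* **Hosmer–Lemeshow** — risk deciles (stable sort; empty groups collapsed
  with a warning), chi-square with g − 2 degrees of freedom (g = 10). The
  g − 2 reference distribution assumes the probabilities were *fitted* to
  the data under test; the calibration-null simulations therefore fit a
  logistic model per replicate. With externally fixed probabilities the
  statistic is ~χ²(g) and the test over-rejects — a property of the test,
  not of this implementation.
* **2 × 2 metrics** — accuracy, sensitivity, specificity, PPV, NPV; 0/0 is
  reported as 0.

## Phantom cohorts

Each subject is an elliptical lesion (random semi-axes 8–13 px, random
rotation and centre jitter) on a smooth background, rendered at 64 × 64 in
two modalities sharing geometry. The class signal is deliberately
**texture-borne**:

* within-lesion texture is Gaussian-filtered noise with class-dependent
  correlation length (NM 2.0 px, PM 0.8 px — PM lesions are rougher),
  demeaned and variance-normalized inside the lesion, so class means *and*
  marginal variances of lesion intensity are equal by construction;
* PM lesions add a 3-px graded alpha-blend "infiltration" band at the mask
  boundary (NM margins are sharp), emulating infiltration into surrounding
  tissue;
* pseudo-PET shares the geometry, with uptake heterogeneity 0.55 (PM) vs
  0.25 (NM) and a 1-px resolution blur;
* per-subject nuisance variation — lesion-mean jitter ±0.1, background
  jitter ±0.05, sensor noise sd 0.03 — is label-independent, emulating
  acquisition variability and keeping absolute intensity uninformative.

These defaults were fixed once, by design-time pilot runs, to produce a
gray-only pilot distinctly above chance but below the boosted model —
the qualitative regime the methodology targets. Phantom experiments use a
desk-scale candidate bank of 10 texture-sensitive features (2–3 per family)
rather than all 75, and cohorts of 25 + 25 subjects split 60/40; these are
problem-size choices, the full bank remains available.

What the phantoms do **not** emulate: anatomical context, attenuation and
partial-volume physics, scanner-specific noise spectra, contouring
variability, 3D structure, or class-conditional intensity differences.
Passing phantom tests therefore shows the *machinery* is correct and the
protocol behaves as designed when the class signal is textural; it does not
certify clinical performance on real PET/CT.

## Known limitations

* 2D only; no shape or first-order feature families (the map bank is
  texture-only by design).
* The tiny base is not a pretrained ImageNet backbone; the protocol, not the
  weights, is the artifact. ResNet-scale bases can be plugged in where the
  compute exists.
* Greedy pruning minimizes removals only heuristically; on adversarial
  correlation graphs a smaller retained-set-complement may exist.
* The Hosmer–Lemeshow p-value is approximate in small samples and after
  group collapse.
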