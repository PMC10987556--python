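# Methods

## Problem and pipeline

A hand radiograph for rheumatoid-arthritis scoring shows both hands; the
20 PIP/IP and MP finger joints must be located and each classified for
two special findings scored in the modified total Sharp score: ankylosis
(bony fusion) and subluxation/dislocation (pooled).  The thumb IP joint
carries no subluxation annotation, so the subluxation task covers 18 of
the 20 joints.

`jointscan` runs two independent multibox detectors (one per finding
task), tiles each over the whole image, removes duplicates, and fuses the
two box lists into one dual-labelled joint list:

1. **Tiled inference** — windows of side `window` (300 px) at stride 150 px,
   origins `0, 150, 300, …` while inside the image, zero padding beyond
   it.  Scanning happens on the half-resolution image (films are stored
   at 2010×1670, 1024 gray levels; processing at 1005×835 keeps joint
   boxes large relative to the detector window).
2. **Per-detector selection** — confidence filter (strict `> t_conf`,
   default 0.9), greedy NMS (inclusive `≥ t_IoU1`, default 0.15), top-M
   cut (M1 = 20, M2 = 18).  The confidence of a box is the larger of its
   two finding-class probabilities; the background probability is
   excluded so background-dominated boxes cannot reach the top-M stage.
3. **Ensemble merge** — cross-detector pairs with IoU ≥ `t_IoU2` (0.45)
   merge one-to-one (greedy, by descending combined confidence); the
   fused box keeps the geometry and confidence of the higher-confidence
   member (tie → ankylosis member) and carries both source labels.
   Unpaired boxes get the explicit negative label `c_neg` (probability 1
   on *finding absent*) for the missing task.  The final list is cut to
   the M1 highest confidences only when M1+1 or more candidates remain.
4. **Evaluation** — predictions match ground truths greedily by
   descending IoU, one-to-one; a joint is detected iff its matched IoU is
   strictly above 0.45.  Confusion counts for each finding task cover
   *detected joints only*: an undetected joint is a detection failure and
   deliberately does not appear as a classification false negative, so
   detection rates and classification tables decouple.  Per-fold metrics
   use the standard 2×2 formulas; 0/0 ratios are undefined (NaN) and are
   excluded from the unweighted fold average.  Reported tables round
   half-up to two decimals.

## Detection model

Each detector classifies a deterministic grid of default (anchor) boxes
into three classes — background (0), finding present (1), finding
absent (2) — and regresses center/size offsets
`((g_cx−d_cx)/d_w, (g_cy−d_cy)/d_h, log(g_w/d_w), log(g_h/d_h))`.

Matching: every ground truth is force-matched to its best-IoU default
(greedy over pairs in descending IoU, so conflicts resolve toward the
larger overlap), and any further default whose best IoU reaches 0.5 joins.
The loss is `L = (1/N)(L_conf + L_loc)` with N the number of matched
defaults, smooth-L1 localisation over matched boxes, and softmax
cross-entropy over matched boxes plus hard negatives mined at 3:1 by
descending background cross-entropy.

Two choices here are deliberate departures from a bare-bones multibox
recipe, both needed at this model scale:

* **Ignore zone for negatives** (`neg_iou_max = 0.3`): unmatched defaults
  overlapping a ground truth at IoU ≥ 0.3 receive no gradient at all.
  Without it, hard-negative mining preferentially selects the near-match
  defaults straddling a joint and trains the joint's appearance toward
  background while the matched neighbours train it toward a finding
  class; a compact network averages the two signals and plateaus at
  ~0.5 confidence.  With the ignore zone the same configuration converges
  cleanly (this is the familiar "ignore region" of region-proposal
  training).
* **Center-inclusion for crop targets**: when a training window cuts a
  joint, the joint stays a positive target if its center is inside the
  window (its box may extend past the edge).  Full-containment would
  label the visible part of a cut joint as background — the same
  conflicting-signal problem in a different guise.

The network is written directly in numpy: conv3×3 (im2col + matmul) →
ReLU → 2×2 maxpool blocks, with per-feature-map classification and
localisation heads whose channel layout follows the default-box order.
Backward passes are hand-written and exact — verified against central
finite differences at 1e-4 — which is also what Grad-CAM consumes.  All
computation is deterministic for a fixed seed.

The desk-scale configuration uses a 64-px window, blocks of
(16, 32, 32, 48) channels, and two detection feature maps (8×8 at scale
0.3 and 4×4 at scale 0.55, aspect ratios 1, 2, ½ → 240 default boxes).
The reference full-size grid — 300-px window, six feature maps
(38, 19, 10, 5, 3, 1), scales 0.1–0.9, 8732 boxes — is available as
`ssd300_grid_config()` for box arithmetic and larger builds.

Training hyperparameters (deployment defaults): Adam with lr 0.001,
betas (0.9, 0.999), weight decay 0.0005; 200 epochs, batch 16.  Every
epoch draws one random crop per annotated joint per image (the crop is
positioned uniformly among windows fully containing that joint), so 210
training images yield 4200 ankylosis-task crops per epoch.  Augmentation
applies four transforms independently with probability 0.5: intensity
jitter (gain 0.8–1.2, offset ±0.1 — the "colouring" step, interpreted as
brightness/contrast jitter), crop-resize (zoom 0.8–1.0), rotation by a
multiple of 90°, and horizontal flip; box annotations transform
consistently, and boxes whose center leaves a crop are dropped.
Grayscale input is replicated to three channels.

## Grad-CAM

For feature map `A` (channels k) and class c, `α_k` is the spatial mean
of `∂y_c/∂A_k` and the map is `ReLU(Σ_k α_k A_k)`; gradients of
non-target classes are zeroed.  A detector emits one logit triple per
box, not a single class score, so `y_c` must be defined: here it is the
summed class-c logit over the boxes that survive the confidence filter
(falling back to the single most confident box when none passes).  This
weights exactly the boxes that drive the final prediction; other
reductions (single-box, all-box) are possible and the choice is exposed
through the `t_conf` argument.  Upsampling to window size is bilinear and
used only for overlay rendering; the raw map is preserved.

## Synthetic phantoms

The generator emulates the *annotation arithmetic and pipeline geometry*
of a two-hand film, not radiological appearance: two hand regions of five
bright finger columns each (thumb shorter), each finger interrupted by
two darker gap bands — the distal joint (PIP, or IP for the thumb) and
the MP joint — over a dark background with additive Gaussian noise
(σ = 0.02 of full scale), stored as 10-bit intensities.  Joint boxes are
squares of 1.6× the finger width centred on the gap, which keeps them
well under `window − stride` so every joint fits fully inside at least
one scan window.

Findings: ankylosis fills the gap at bone intensity; subluxation shifts
the segment distal to the joint laterally by 45% of the finger width.
Prevalences default to the study rates (157/5200 ≈ 3.0% ankylosis,
60/4680 ≈ 1.3% subluxation).  Flags are drawn once per patient-joint and
shared by the patient's two timepoints (ankylosis does not remit between
films); the second film re-renders the same hand with small geometric
drift.  Expected positive counts are unchanged by this sharing, but the
variance is twice that of an independent per-joint draw — the
prevalence test in the suite accounts for this.

A dataset of n images is n/2 patients × 2 timepoints; 260 images give
exactly 5200 ankylosis-task and 4680 subluxation-task joint annotations.

What passing on phantoms does **not** show: robustness to real
radiographic variation (bone texture, carpal overlap, prosthetics and
metal artifacts, exposure differences, severely deformed hands with
overlapping joints).  The phantoms establish that the pipeline machinery
— tiling, decoding, NMS, fusion, evaluation — is correct and that the
training loop can learn a gap-vs-filled-gap discrimination; they say
nothing about clinical performance.

The **oracle detector** emits ground-truth boxes (optionally jittered,
dropped out, or duplicated per covering scan window) with confidences
drawn above the deployment threshold.  It is a test double for a trained
detector, used to verify the inference, ensemble and evaluation stages
independently of training: with exact oracles the full pipeline is
lossless (100% detection, perfect confusion counts), and with one oracle
degraded by 10% dropout the ensemble restores 100% detection while the
degraded path alone stays below it.

## Cross-validation split

Images are split at the *patient* level (both films of a patient stay
together, preventing leakage between a fold's train and test sides).
Patients are stratified into finding-positive and finding-negative
strata, shuffled deterministically, and dealt round-robin into five
groups, spreading positives as evenly as integer counts allow.  With 260
images the groups hold 26 patients (52 images); the published protocol
tests on 50 images per fold, so each fold's test set is trimmed to whole
patients fitting `test_size` (default: the full group; 50 reproduces the
210-train/50-test arithmetic) and *all* remaining images train.  The
trim size is a parameter because 5 × 50 accounts for only 250 of 260
images and the remainder handling is otherwise unspecified.

## Scaled-down study sizes

Everything runs CPU-only at desk scale; the suite's problem sizes are
chosen accordingly and stated here as the package's own test conditions:

* pipeline identity / compensation checks: 20 full-size phantoms
  (1005×835) with oracle detectors;
* annotation arithmetic: the full 260-image simulated study;
* learning smoke check: 50 training + 10 held-out phantoms at 256×224
  (finger geometry scales with the raster, so joint boxes ≈ 16 px fit
  the 64-px window), ankylosis task, 15 epochs, fixed seed.  Success is
  per-window recall ≥ 0.9 at IoU > 0.45, evaluated at a recall-oriented
  confidence threshold of 0.5 rather than the deployment filter of 0.9
  — the deployment threshold presumes a fully trained model, and the
  smoke check asks whether learning happens, not whether the model is
  production-calibrated.  The fixed-seed run converges to ≈0.96.

## Numerical and convention notes

* Boxes are continuous pixel coordinates, origin top-left, x rightward,
  y downward, stored center/size; corner form is derived.  IoU of
  degenerate (zero-area) overlap is 0, and results are clipped to [0, 1]
  against floating-point drift.
* Annotation JSON stores boxes at full resolution with a
  `coordinate_scale` field (0.5 default) recording the working resize;
  legacy corner-format boxes are converted on read and logged.
  10-bit intensities normalise as value/1023.
* Threshold conventions: confidence filter strict (`>`), NMS inclusive
  (`≥`), detection success strict (`>` 0.45).  NMS ties keep the earlier
  box in scan order; top-M and fusion ties resolve by list order —
  every stage is deterministic.
* The combined loss is normalised as `(L_conf + L_loc)/N` and defined 0
  at N = 0.  Batch training pools sums and N over the batch before
  normalising, so the batch objective equals the pooled-window formula.
* Checkpoints are single `.npz` files embedding weights, task id, grid
  config, seed and loss history.

## Known limitations

* Carpal and foot joints, erosion/JSN scoring and two-timepoint score
  differences are out of scope.
* The compact detector is sized for phantoms; clinical-scale training
  would need the full-size grid, a far larger backbone and GPU time.
* Boxes straddling window edges are kept as decoded; edge truncation is
  a known failure mode of single-window detection and is only mitigated
  by the overlapping-window scan and the ensemble, not solved.
* Metric fold-averaging is unweighted, so folds with few positives get
  equal say; undefined (0/0) fold metrics are silently excluded from the
  average.
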