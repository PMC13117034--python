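# Methods

## Problem setting

A patient's pre-treatment 3D scan is a *bag* of axial slices with only a
patient-level (bag-level) outcome label available; which slices carry the
pathology is unknown. The package implements a weakly-supervised
multiple-instance learning (MIL) model for such data — a dual-layer
attention mechanism with an adaptive bag embedding — together with the
multimodal pipeline around it: univariate screening and lasso selection of
clinical/dosimetric and engineered (radiomics-style) image features,
concatenation fusion with the learned deep features, and a sigmoid MLP risk
predictor, evaluated with patient-level splits, 5-fold cross-validation and
bootstrap AUC intervals.

## Model

### Instance extraction

Volumes are min-max rescaled to [0, 1] per volume, x' = (x − min)/(max −
min) (an opt-in flag rescales to [−1, 1]; the two conventions differ only
by an affine map the first convolution absorbs). A small headless 3D CNN
turns a volume into k instance vectors h_1..h_k: stacked 3×3×3 convolution
blocks, each with per-slice normalization, ReLU and average pooling
(default: one stride-2 depth pooling in the first block, so each depth
position of the final feature map — one instance — summarizes a window of
two adjacent slices). Each instance's spatial extent is flattened and
linearly projected to d = 32 dimensions, and records its source depth
interval (provenance), which is how attention scores are later attributed
to slices. A per-slice-window granularity and a pretrained-parameter
loading hook exist as configuration options.

The normalization standardizes each channel over a slice's in-plane
positions (learnable per-channel scale/shift) and is load-bearing twice
over. First, without any activation normalization the conv stack does not
escape its initialization within a desk-scale epoch budget. Second, the
statistics must be per-slice, not per-volume: per-volume statistics include
the lesion's contribution, shifting *every* slice's normalized features in
positive bags — a bag-level leak through which the classifier can succeed
without localizing anything (observed as perfect bag AUC with chance-level
instance attention). Per-slice statistics keep instances conditionally
independent given their own content; they use no batch statistics, so
inference is deterministic.

### Dual-layer attention with adaptive bag embedding

1. **Attention MIL pooling.** Gated-tanh attention scores every instance,
   a_k = softmax_k(w^T tanh(V h_k^T)), and pools Z = Σ_k a_k h_k.
   Σ_k a_k = 1 by construction.
2. **Top-M critical-instance selection.** The M highest-scoring instances
   are selected (descending score, ties broken by ascending index). The
   selection is hard: no gradient flows through the indices.
3. **Adaptive M.** A small controller MLP (one hidden layer of width 16,
   input = softmax of the top-M scores, padded/truncated to length 8 with
   renormalization) emits M′ = clamp(round_half_up(σ(MLP(p))·k), 1, k),
   which becomes the next forward pass's M. M starts at ⌈k/2⌉, is updated
   once per bag per training forward, and is frozen at the running median
   of its trajectory for inference, making evaluation deterministic.
   Because both the rounding and the index selection block gradients, the
   controller itself is exercised but not trained; with near-zero output
   its proposal stays near k/2.
4. **Distance calibration.** Instances are projected to queries and values,
   q_k = W_q h_k, v_k = W_v h_k. The second attention weight averages, over
   the selected critical instances c_m, the softmax (over instances n) of
   inner-product similarity: D_k = (1/k) Σ_m softmax_n(⟨q_n, q_cm⟩)[k].
   Under this printed 1/k normalizer Σ_k D_k = M/k exactly; a 1/M variant
   (Σ D = 1) is selectable. One head by default; with several heads D is
   averaged across heads.
5. **Bag embedding.** B = Σ_k D_k v_k; its flattened form is the patient's
   deep feature vector (width = projection dim, default 32).

### Stage-1 training

Backbone, both attention layers and a linear-sigmoid head train end to end
with binary cross-entropy on bag labels (Adam, defaults lr 1e-4, weight
decay 1e-5, batch 4, ≤100 epochs, early-stopping patience 15 on a
stratified 20% validation split). The head reads concat(Z, flatten(B)).
This is a deliberate choice: with hard top-M selection the only
differentiable influence of the first-layer attention is through Z, so a
head on B alone would leave w and V untrained. Early stopping *halts*
training and keeps the final weights; on bag-level synthetic data the
validation loss saturates near zero several epochs before the attention
ranking finishes sharpening, so restoring a best-validation snapshot would
systematically return models whose bag predictions are perfect but whose
attention has not yet localized.

All numerics run in float64 on the package's own small tape-based autodiff
core, which implements exactly the operations these models need; gradients
are verified against finite differences in the test suite.

### Tabular selection chain

Continuous features are z-scored (sample SD, ddof = 1; zero-variance
columns dropped with a warning). Screening uses a pooled-variance two-sample
t-test for continuous and an uncorrected chi-square for categorical
features; selection is p < α (strict, per the formal statement; an
inclusive ≤ flag exists), α = 0.05. The lasso minimizes
(1/2M)Σ(y − β0 − xβ)² + λ‖β‖₁ with an unpenalized intercept; λ is chosen on
a 100-point log grid from λ_max down to 10⁻⁴λ_max (0.002 always appended)
by 5-fold cross-validated MSE, ties broken toward the larger λ. The lasso
is fit against the binary label with squared error, as the objective is
printed. The engineered-feature space schema enumerates 758 identifiers:
14 shape features on the original image plus 8 wavelet sub-bands (all
high/low-pass combinations along three axes) × (18 first-order + 75
texture features); image-based extraction itself is a delegated adapter
hook.

### Fusion and prediction

Selected blocks are concatenated per patient in fixed clinical → radiomics
→ deep order, aligned on patient id; an ablation flag permits absent
blocks, recorded in the layout. The predictor is a one-hidden-layer (width
32) MLP with sigmoid activations trained with BCE under the same optimizer
protocol; inputs are re-standardized with training-fold statistics (blocks
arrive on different scales). Decision threshold is fixed at 0.5 (class 1
iff p ≥ 0.5).

### Evaluation

Splits are stratified at the patient level (per-stratum round-half-up test
counts); 5-fold plans are stratified with fold sizes within one. AUC is the
Mann–Whitney statistic with half credit for ties; its 95% CI is a
stratified percentile bootstrap (2000 replicates). The ablation harness
trains six variants on one shared split: clinical-only, radiomics-only,
CT with mean-pooling MIL, CT with the dual-attention model, and the two
fused models.

## Synthetic cohort

The generator emulates the statistical structure the method assumes, not
the appearance of real scans:

- **Volumes**: Gaussian noise (SD 1) plus a fixed bright border frame
  (intensity 8) that anchors the per-volume min-max range. The anchor
  matters: without it, positive volumes (whose maximum is raised by the
  lesion) are rescaled differently from negative ones, leaking the bag
  label into every instance and removing the incentive to localize.
- **Lesions**: each positive patient gets 1–2 key slices, each carrying a
  bright ellipse (additive shift, default 3× noise SD; center and semi-axes
  jittered) confined to that slice, so the signal is slice-attributable.
  Bag label = 1 iff ≥1 key slice (the MIL constraint, asserted for every
  generated patient).
- **Clinical table**: six categorical null features and five continuous
  dose-volume metrics (V5–V30, mean lung dose) with control-group means/SDs
  typical of thoracic radiotherapy cohorts and additive positive-class
  shifts of roughly 0.2 pooled SD by default — detectable at the default
  cohort size (n = 670) but not at toy sizes.
- **Radiomics-style table**: 758 Gaussian columns, the first 15 shifted by
  0.8 in positives.
- One integer seed drives labels, volumes, lesions and both tables through
  named SeedSequence sub-streams; identical configs are bit-identical.

What the generator does **not** emulate: anatomical texture, inter-slice
correlation of real organs, scanner effects, feature correlation structure
of real radiomics, or label noise. Passing recovery tests therefore shows
the machinery optimizes and localizes as designed under its own
assumptions; it says nothing about clinical performance.

## Desk-scale benchmark

The recovery benchmark (`daaemil.benchmark`) uses n = 120 patients,
32×32×16 volumes, lesion effect 3× noise SD, an 80/20 patient split and
seeds {1, 2, 3}. Stage-1 training runs at lr 1e-3 for ≤40 epochs (patience
15), the fused predictor at lr 1e-2 — desk-scale settings chosen once for
this problem size; the clinical-protocol defaults remain on the training
functions. The benchmark cohort's dosimetric shifts are ~0.75 pooled SD so
that per-feature t-statistics at n = 120 match what the default shifts
reach at full cohort size; the faithful small shifts are exercised by a
separate n = 4000 screening-chain test. Checks: pooled instance-level
attention ROC-AUC ≥ 0.8 per seed (planted vs background instances over all
positive bags), and fused dual-attention AUC ≥ the mean-pooling variants in
≥2 of 3 seeds (ties count: at this signal strength several variants reach
AUC 1.0 on a 24-patient test set).

## Numerical choices and degenerate inputs

- Softmaxes subtract the max before exponentiation; sigmoids use the
  two-branch stable form; BCE is computed on logits.
- Ties in top-M break by ascending index; ties in λ-CV toward larger λ;
  round-half-up for M′ and for stratified test counts.
- k = 1 bags force M = 1, a = [1], D = [1], B = v₁.
- Constant volumes cannot be min-max normalized (error); zero-variance
  columns are dropped; degenerate contingency tables are skipped with a
  warning; single-class label vectors are rejected wherever a two-class
  statistic is required (AUC raises; other metrics are still reported in
  the error message).
- Empty selection results fall back (with warnings) to the screened or
  all-continuous candidate set inside the ablation/pipeline harness, so an
  uninformative modality degrades to chance-level input instead of
  aborting a run.

## Known limitations

- The adaptive-M controller is architecturally present but untrained (no
  gradient path through rounding + hard selection); its practical effect is
  M ≈ k/2 at init. Training it would require a relaxation the source
  formulation does not define.
- The backbone is a tiny 3-block CNN, not a full C3D; widths/pools are
  configurable and a parameter-loading hook exists, but no pretrained
  weights ship with the package.
- Image-based radiomics extraction is out of scope (schema + synthetic
  tables only).
- Bootstrap percentile intervals are known to undercover slightly at small
  n; the CI coverage test uses a loose ≥88% bound at nominal 95%.
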