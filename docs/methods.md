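# Methods

## Problem and model

`rccgrade` implements a weakly-supervised pipeline for binary grading of
clear-cell renal cell carcinoma (ccRCC) from per-patient stacks of 2-D tumor
region-of-interest (ROI) images. Fuhrman grades I–II are treated as the
low-grade class (label 0), grades III–IV as high-grade (label 1). Labels are
pathology results and therefore live at the *patient* level; every image in a
patient's stack inherits the patient's label as its observed label. Three
data pathologies drive the design:

1. **Domain shift.** Natural-image pretraining transfers poorly to CT crops,
   so the feature extractor is pretrained on the *same* images with a
   self-supervised rotation-prediction pretext task: each image is expanded
   into its four clockwise quarter-turns, labeled 0–3, and a backbone +
   linear head is trained to classify the rotation. Quarter-turns are index
   permutations, so the pretext data are exact and label-free with respect to
   grading semantics.
2. **One-directional label noise.** Some lesions from high-grade patients
   lack discriminative character: their observed label is 1 but their
   appearance is that of a low-grade lesion. Low-grade labels are trusted.
   With an assumed noise rate α among high-labeled samples, the training
   objective mixes plain cross-entropy L_CE with a low-grade-only term
   L_CE0 = −(1/N) Σ_i 1[y_i=0] log p_i0:

       L_mix = α · L_CE + (1−α) · L_CE0

   The auxiliary term only ever rewards low-grade probability on samples
   already labeled low; it never penalizes a high-labeled sample for hedging
   toward low, which is the sense in which the loss tolerates label errors
   in the high class. The weighting direction (α on L_CE) is implemented as
   the equation is printed in the source method description, although the
   accompanying prose can be read the other way; a `mixing="complement"`
   flag swaps the two coefficients, and a `noise_term="flip_to_low"` flag
   replaces L_CE0 with −(1/N) Σ_i log p_i0 over *all* samples (learning from
   a copy of the data with every label set to low), which is another
   defensible reading. Defaults follow the printed equation. Default α = 0.4.
3. **Class imbalance.** Roughly 60/40 low/high at the patient level. Each
   class's loss contribution is scaled by a weight λ_j. The combined
   objective is

       L_total = −α(1/N) Σ_i Σ_j λ_j l_ij log p_ij − (1−α)(1/N) Σ_i λ_0 l_i0 log p_i0

   The source method never states the λ formula, so two schemes are
   provided. `inverse_frequency`: λ_j = N/(2 n_j), the standard balanced
   weighting (default). `noise_adjusted`: because class-0 samples receive
   both terms (total per-sample coefficient λ_0, vs. αλ_1 for class 1), the
   expected per-class contributions are equalized by solving
   λ_0 n_low = α λ_1 n_high with λ_0 + λ_1 = 2. The normalization λ_0+λ_1=2
   keeps the loss scale comparable across schemes.

**Patient aggregation.** Per-image high-grade probabilities g_1..g_M are
collapsed with G = max(g_1,…,g_M): the call follows the most severe-looking
image. Max is monotone idempotent (adding an image scoring below the current
maximum changes nothing).

**Ensembling.** K independently trained models are combined per patient as
F = Σ γ_k G_k / Σ γ_k. The weights strip the shared AUC decile:
γ_k = AUC_k − d, with d the common (or, as a continuous extension, the
minimum) decile of the models' development-side AUCs. Stripping the shared
digit stretches small AUC differences into large relative weight
differences, e.g. (0.864, 0.822, 0.830, 0.859) → (0.064, 0.022, 0.030,
0.059). AUCs feeding the rule are measured on the development cohort — using
validation AUCs would leak the evaluation data into the model — and the CLI
requires the AUC source to be passed explicitly. An AUC exactly on the
minimum decile boundary would yield weight 0 and raises; the `raw_auc` rule
is the fallback.

## Training protocol

Two phases share one backbone contract (batch of H×W×3 images → feature
matrix). Phase 1 (pretext): linear head, 4 outputs, plain CE, SGD. Phase 2
(development): backbone weights copied bitwise from the pretext model; a
freshly initialized nonlinear projection head (dense → ReLU → dense, hidden
width = feature dim, 2 outputs); loss L_total; SGD with two parameter groups.
The projection trains at the base learning rate, the already-useful backbone
at `backbone_lr_ratio` = 0.1 times that; the ratio is enforced at every
step. Schedule: linear warm-up to base_lr = 0.1 over 5 epochs (evaluated at
epoch+1 so the first epoch trains), then cosine decay base_lr·½(1+cos πt) to
a floor of 0, at per-epoch granularity. Weight decay 1e-4 (coupled L2).
Development-time augmentation is a random quarter-turn plus a 0.5-probability
horizontal flip — lossless pixel permutations; no augmentation during the
pretext phase, where rotation *is* the label. Batch size defaults to 32
(never stated in the source method); the desk profile uses 64. Warm-up
epochs count inside the epoch budget. Full-scale epoch counts are 60
(pretext) and 100 (develop); the desk profile uses 20/25.

The training backend is a small numpy engine (`rccgrade.nnet`): stride-1
same-padding convolutions (im2col), ReLU, 2×2 max pooling, global average
pooling and dense layers with hand-derived backward passes, verified against
central finite differences in float64 to ~1e-7 relative error. The default
backbone is a 4-block CNN with channel widths (8, 16, 32, 32), ~15k
parameters, sized for 32 px inputs; pooling three times constrains input
edges to multiples of 8. Alternative backbones register through
`nnet.BACKBONES` behind the same contract. Projection/head initialization is
fan-in-scaled ("He") normal; everything is deterministic given the init and
training seeds. Probabilities are clamped at ε = 1e-12 before logs.

## Synthetic cohort generator

No public ccRCC grading cohort with per-patient CT stacks exists, so
`synthgen` emulates the structure of such data: N patients, ~60/40 low/high
imbalance, 10–25 images per patient (targeting the ~17.7 images/patient of
the motivating cohort: 12,469 images / 706 patients), pre-resize edge
lengths 24–96 px, acquisition years 2010–2019 with a configurable fraction
of patients before the 2018 development/validation cutoff.

Appearance is a phantom, not a CT simulation: Gaussian-textured background,
one bright ellipse whose semi-axis fraction (0.20/0.25/0.33/0.40 of the
edge for grades I–IV) and internal multi-scale speckle amplitude
(0.04/0.07/0.14/0.20) grow with the generating grade. High-grade lesions are
therefore larger and more heterogeneous by construction, with a bright-pixel
area statistic separating true-label groups by more than one SD — the desk
learning problem is solvable on purpose. A mild vertical background
intensity gradient (amplitude 0.12) provides an orientation statistic: real
CT crops carry anatomy-driven orientation cues, and without *any* such cue
the four rotations of an image are statistically exchangeable and no
learner could beat chance on the pretext task, which would make the
pretraining phase untestable.

Label noise is injected at the patient level (pathology labels are
per-patient): each high-labeled patient is independently corrupted with
probability `noise_rate_true` (default 0.4), in which case *all* of its
images are drawn from a low-grade appearance distribution and carry
`true_label = 0` while `observed_label` stays 1. Low-labeled patients are
never corrupted. What the generator does **not** model: Hounsfield
calibration, 3-D structure, scanner effects, intra-patient lesion
correlation beyond shared grade, or realistic ccRCC morphology — the
appearance parameters are knobs, not claims. Passing tests on this phantom
show the pipeline's mechanics (optimization, transfer, aggregation,
ensembling, directional benefit of each component) work; they say nothing
about absolute performance on clinical data.

## Desk-scale experiment

The component analysis (`experiment.run_ablation`) uses one fixed synthetic
cohort — 80 patients, 60 development / 20 validation by acquisition year,
noise rate 0.4, 40% high-grade — and four cells: `base` (plain CE),
`pretext` (+rotation pretraining), `loss` (+mixed loss and inverse-frequency
reweighting), `full` (all components). Each cell trains under 5 training
seeds (pretext runs shared between the two pretrained cells of a seed);
medians over seeds support directional comparisons only. The full-method
models of the first four seeds form the 4-model ensemble, weighted by
decile-stripped development-side AUCs (falling back to raw-AUC weights if a
weight would be non-positive). A separate noise-free run
(`experiment.run_noise_free`) is the positive control. Problem sizes
(80 patients, 32 px, 20+25 epochs, 5 seeds) are the package's desk profile,
chosen so the whole grid runs in minutes on one CPU.

Per-cell ACC/SEN/SPC are reported at the neutral threshold 0.5 on the
aggregated score (the source method states no threshold). Note that max
aggregation over ~17 images and the low-grade-rewarding auxiliary term both
shift score calibration, so 0.5 can sit far from the Youden point of a
particular run; AUC is the calibration-free comparison, and
`classification_metrics` accepts any threshold for operating-point studies.

## Numerical and degenerate-input choices

* Percentages in cohort statistics and classification metrics are rounded
  half-up to one decimal (374/592 → 63.2), matching standard clinical-table
  arithmetic.
* ROC ties take the half-credit (Mann–Whitney) convention; curve and area
  come from scikit-learn's trapezoidal construction and are tested against
  brute-force pair counting.
* `resize_or_pad` preserves aspect ratio (bilinear), then center-pads with 0
  — ROI backgrounds are already suppressed; whether the original protocol
  preserved aspect is unstated, so this is a package decision. Pad mode on
  an oversize image raises rather than cropping.
* Single-channel images are replicated to 3 channels.
* Empty cohorts, single-class cohorts (sen/spc undefined), zero class
  counts, non-square pretext images, out-of-range grades and epochs all
  raise informative errors rather than degrading silently.
* Max-pool gradient flows to the argmax (first index on exact ties).

## Known limitations

* Absolute clinical performance is out of reach by construction: the
  motivating cohort is private, and the phantom is far easier than CT.
* The numpy backend targets desk scale; it is single-threaded per BLAS and
  has no GPU path. Full-size residual backbones are out of scope, though the
  backbone registry accepts any implementation of the contract.
* The α-direction ambiguity in the mixed loss is surfaced as a flag, not
  resolved; both readings are available.
* One acquisition year per patient is assumed (repeat scans are not
  modeled).
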