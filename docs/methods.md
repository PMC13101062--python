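# Methods

This note documents the models, procedures, defaults, and design decisions
behind `oraltriage`, and what the synthetic-data results do and do not show
about real clinical data.

## Task and data model

The unit of classification is an anatomic *site* of the oral cavity. Each
site carries: a three-way expert referral label (*Do Not Refer*, *Refer for
Other*, *Refer for Suspicion of Precancer/Cancer*), one or more captures —
each a white-light (WL) image, an autofluorescence (AF) image, and a binary
oral-mucosa annotation mask — and a link to its patient's risk-factor
record. For classification the two refer categories pool to the positive
class; this binarization is fixed pipeline-wide (`binarize_referral`) and
is the default because both refer reasons demand specialist evaluation.

Three cohorts model the continual-learning setting:

| cohort | role | referral prevalence |
|---|---|---|
| high_prevalence | prior development data | ~50–80% |
| healthy | prior development data | 0% |
| low_prevalence | deployment / holdout population | ~2–3% |

## Synthetic cohort generator

No public dataset accompanies this task, so the generator is first-class,
tested code. It emulates the *structure* of the clinical data — labels,
patient grouping, contralateral-normal controls, missingness, paired
rasters with masks — rather than oral-cavity photometry.

**Patients.** Ages are drawn from a truncated normal (mean 49.2 y, SD
15.1 y, range 18–90 by default); categorical demographics and habits come
from configurable vocabularies with community-dental-clinic-like rates
(52% female, 14% cigarette smokers, 54% alcohol users, …). Missingness is
injected per field at configured rates (e.g. 30% unrecorded race, one in
fifty missing ages in the low-prevalence profile).

**Labels.** By default each site is referred with probability
`refer_prevalence` (Bernoulli), and a configured fraction of referrals is
relabeled *Refer for Other*. The `exact_*` fields instead pin exact counts,
which the `paper_shaped` profile uses to reproduce a published dataset
shape deterministically. Lesions are placed patient-first: every lesion
patient has a primary lesion site, and surplus lesions land on further
sites of already-lesioned patients, concentrating referrals in a realistic
number of patients. Contralateral-normal flags (clinically normal mirror
sites of lesion patients, imaged as internal controls) are generated only
in the high-prevalence cohort — the only cohort where the rehearsal split
drops them.

**Images.** Phantoms are parametric ellipses: a textured mucosa ellipse on
a dark background, WL pinkish and AF green-dominant, with Gaussian pixel
noise and a smooth low-frequency texture field. Referral sites carry a
lesion ellipse inside the mucosa, blended toward a pale keratotic color in
WL (`wl_contrast`) and with multiplicative green-channel attenuation in AF
(`af_loss`) — the loss-of-fluorescence signature the real modality looks
for. The painted footprint is recorded in `lesion_mask` (generator-internal
truth; never an input to the model). Default canvas is 256×256 so the
crop-and-resize path is non-trivial; profiles use 64×64 for speed. Each
capture's RNG stream derives from the cohort seed and the capture id, so
rasters are bit-identical across runs and independent of rendering order.
Sites marked as QC failures are rendered without their AF frame.

**What this does not model:** real mucosal texture and color statistics,
specular highlights, focus/illumination variation, inter-operator
differences, or any correlation between risk factors and lesion status
(risk factors are generated independently of labels). Passing tests
therefore demonstrate that the *pipeline machinery* — splitting rules,
training mechanics, rehearsal handoff, metric arithmetic, attribution — is
correct, not that any particular clinical accuracy is attainable.

## Preprocessing

QC keeps a site iff at least one capture has both a WL and an AF frame
(optionally also a mean-intensity floor inside the mask, as a crude
illumination check). The clinical analogue included manual focus and
illumination review; the pairing rule is the only programmatically
reproducible criterion, so it is the default.

Images are masked (pixels outside the mucosa annotation zeroed), cropped to
the tight axis-aligned bounding box of the mask (half-open pixel intervals,
origin top-left), and resized to 224×224 with bilinear interpolation.
Aspect ratio is *not* preserved and no padding is added; this is the
simplest reading of a crop-then-resize pipeline and is configurable via
`out_size`. A property guaranteed by construction and enforced by test:
zeroing outside the mask before or after cropping yields identical output,
i.e. nothing outside the annotation can leak into the model input.

Standardization is per modality (WL and AF have radically different color
distributions) and per channel, with population statistics over all
training-split pixels, SD floored at 1e-6 for degenerate channels. The
statistics are fitted once per training stage on that stage's *training*
split only — never validation or test (leakage guard asserted in tests).

Augmentation (random horizontal flip p=0.5, rotation within ±10°) is
implemented, applied only in training mode, and **off by default**: the
reproducibility contract (bit-identical reruns) is the default posture, and
augmentation is an opt-in.

## Risk-factor encoding

Eight categorical fields (gender, ethnicity, race, cigarette,
smoking-tobacco, smokeless-tobacco, alcohol, anatomic site label) are
one-hot encoded with vocabularies = categories observed in the training
split plus an "unknown" slot that fires for missing *or unseen* values.
Age is min–max scaled to the training range, with missing ages imputed by
the training mean before scaling. Encoding length is 1 + Σ vocabulary
sizes and is constant across a fitted run; every categorical block sums to
exactly 1. Fitting on the training split only is a deliberate
leakage-avoidance choice. The anatomic-site label is one-hot encoded like
the other categoricals; habit fields are yes/no/unknown three-way one-hots.

## Partitioning

**Priming split** (prior cohorts only): site-level random split, 80–20 by
default, stratified by the three-way referral label with
round-to-nearest training counts per stratum; strata with fewer than two
sites go entirely to train with a warning. This split is deliberately *not*
patient-grouped, preserving the staging of the original two-study design.

**Rehearsal split**: (a) prior sites keep their priming partition, except
contralateral normals of lesion patients, which are dropped (they are
near-duplicates of the patient's normal anatomy and would inflate the
negative class with correlated samples); (b) every new-study referral site
goes to the holdout test set, and grouping dominates — all other sites of a
referred patient follow it into test; (c) the remaining new-study patients
are allocated as whole blocks across train/validation/test to meet overall
partition targets, 52%/13%/35% by default or explicit target counts.

Block allocation is exact by construction: patient blocks are shuffled with
the seeded generator, a suffix-feasibility dynamic program determines which
assignments can still meet the train and validation quotas exactly, and the
forward pass picks uniformly among feasible options per block. When no
exact packing exists (quota not representable as a sum of block sizes), a
largest-remaining-quota greedy pass is used and the audit reports the
achieved counts. `audit_splits` returns machine-readable pass/fail for
patient disjointness (within the new cohort), the referrals-to-test rule,
test-set purity (new cohort only), drop accounting/conservation, and
stratification tolerance.

## Model

Three branches, fused by concatenation:

- **Image branches** (WL and AF, independent weights): a compact CNN
  backbone → global average pooling → linear projection to
  `image_feature_dim` (default 1024) → ReLU. `small_cnn` is the default
  (four 3×3 conv blocks, 16→128 channels, stride-2 downsampling);
  `tiny_cnn` (two blocks) keeps tests and CI profiles fast; `oneconv` is a
  single-conv backbone for attribution unit tests.
- **Risk-factor MLP**: input → 64 hidden → 32 output, ReLU activations.
- **Head**: dropout (default 0.2) + one linear layer → 2 logits → softmax;
  class 1 is "refer". Default concatenated width 1024+1024+32 = 2080.

The engine (`oraltriage.nnet`) is deliberately dependency-light NumPy with
explicit forward/backward passes (im2col convolution, inverted dropout,
Adam, softmax cross-entropy with optional class weights). Single-threaded
CPU arithmetic makes entire training runs bit-reproducible from one integer
seed — which the rehearsal contract (exact tensor-wise weight handoff
between stages) and the test suite rely on. Loss, optimizer (Adam, lr
1e-4), MLP widths, head depth, and dropout are conventional defaults,
all exposed in `ModelConfig`/`TrainConfig`.

**Training loop.** Shuffled mini-batches of 5; up to 120 epochs with a
60-epoch minimum before early stopping may trigger (patience 15 epochs
without validation-loss improvement). The retained checkpoint maximizes
site-level validation AUC, with validation loss breaking AUC ties — on
separable data the AUC saturates early and the tie-break lets later,
better-calibrated and better-adapted checkpoints win; when the validation
set is single-class (AUC undefined) selection falls back to validation
loss with a logged warning. Per-class training composition is recorded in
the history so majority-collapse under 97:3 imbalance is observable.

**Rehearsal.** `prime` trains on the prior data; `rehearsal_train` builds a
fresh network, loads the primed weights, verifies tensor-wise equality
before any update, and trains on prior ∪ new data — full replay of the
retained prior training set, uniformly interleaved by each epoch's
shuffle. No replay subsampling ratio is applied. Note a structural
consequence of the split rules: the new-study training data contains no
referral sites (all are forced into test), so new-domain adaptation is
driven by negatives while the refer decision boundary is maintained by the
replayed prior data.

## Evaluation

Sites with multiple captures are scored by their highest-scoring image
(max aggregation; order-invariant). AUC is computed as the Mann–Whitney
concordance (via scikit-learn; an all-pairs brute-force oracle verifies
equality to 1e-12 in tests). The Youden threshold maximizes sensitivity +
specificity − 1 over the midpoints of adjacent sorted unique validation
scores plus one candidate below the minimum and one above the maximum;
ties break toward the larger threshold (higher specificity). The decision
rule at the boundary is `score ≥ threshold`. The only supported flow
derives the threshold from validation and applies it to a disjoint test
set. Brier score is the mean squared error of the forecast probabilities;
the Brier Skill Score reference is climatology — a constant forecast at
the evaluated set's base rate — so the climatology forecast itself scores
exactly 0 and a perfect forecast scores 1.

## GradCAM++

Attribution is per image branch with the full fused network in the loop:
the forward pass uses both images and the risk vector; the gradient of the
refer logit flows back through the head into the chosen branch; GradCAM++
weights (α = g²/(2g² + ΣA·g³), channel weights Σ α·ReLU(g)) are formed at
the feature maps entering that branch's global pool. The map is
ReLU-rectified, bilinearly upsampled, and min–max normalized per image.
An all-zero map occurs only when every gradient-weighted activation is
non-positive (e.g. the head's connection to that branch is dead). One
caveat: the canonical α formula is not exactly invariant to scaling the
logit (the ΣA·g³ term scales differently from g²); exact scale invariance
holds — and is tested — in the single-active-channel case. The WL branch
is the default overlay target; AF is available. Colormap (jet) and blend
alpha (0.4) are presentation choices; overlays are not promised to be
bit-exact.

## Profiles and problem sizes

`tiny_ci` (separable phantoms with strong lesion contrast, 64×64 canvas,
32×32 analysis size, tiny backbone, ≤30 epochs) exercises every stage in
seconds and reaches holdout AUC ≥ 0.9 at fixed seeds. `paper_shaped` pins
the cohort shapes to a published two-study dataset (313 prior sites =
143 + 170 with 43 contralateral normals; 252 new sites, 6 QC failures, 5
referrals in a ~3%-prevalence population) with partition targets 268/68/180
— the printed dataset totals — rather than the rounded 52/13/35 fractions,
because largest-remainder rounding of those fractions over 516 sites gives
268/67/181. The profile defaults to records-only runs (dataset-shape and
split-audit work); `train_models=True` renders images and runs the model
stages at reduced resolution. The two-domain forgetting experiment
(`rehearsal_vs_finetune`) gives the prior cohort an AF-only lesion
signature and the new cohort a WL-only signature, primes on the prior
domain, then compares rehearsal against plain fine-tuning on prior-domain
validation AUC; these problem sizes (≤60 sites per cohort, 32×32 inputs)
were chosen so the full suite and the acceptance script run in well under
a minute each on one CPU.

## Known limitations

- The phantom generator does not model real oral photometry; clinical
  accuracy claims cannot be derived from it.
- The pretrained-backbone transfer-learning variant of the image branches
  is out of scope; backbones here train from scratch, which is adequate at
  phantom complexity but would underperform on real images at n≈500.
- No bootstrap confidence intervals or calibration curves; no
  cross-validation or hyperparameter search.
- Risk factors are label-independent in the generator, so the MLP branch is
  exercised mechanically (fusion liveness, gradient flow) but carries no
  predictive signal in synthetic experiments.
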