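# Methods

This note documents the modeling choices, the defaults and their
rationale, what the synthetic cohorts do and do not emulate, and the
numerical conventions. It states no empirical claim that the test suite
or `scripts/acceptance.py` does not itself compute.

## Architecture

Each modality has its own encoder producing a width-`d` embedding
(default d = 32), and a single **shared head** — a bias-free linear
projection `d -> h` (default h = 16) followed by an affine classifier
`h -> 5` — serves both branches. Sharing the head is itself an alignment
device: both modalities must become classifiable by the same weights.
The projection carries no bias so that a zero embedding maps exactly to
the classifier bias, which keeps the weight-sharing contract observable
in tests.

The reference encoders are intentionally small so that a full training
run on a synthetic cohort takes seconds on one CPU:

* **Image branch** — three kernel-equals-stride convolution blocks
  (patch sizes 4, 2, 2; channels 16, 32, 64) with ReLU, global average
  pooling, and a linear map to `d`. Kernel = stride means each block is a
  reshape + matmul, with no interpolation or padding edge cases; inputs
  must be divisible by 16 in each spatial dimension.
* **Text branch** — a token-hash bag-of-words featurizer (CRC32 of each
  lowercased, punctuation-stripped token modulo 256 buckets,
  L2-normalized counts) followed by a linear map to `d`. CRC32 rather
  than Python's `hash` keeps the featurization stable across processes.

Heavyweight pretrained backbones are supported only through the
`external_adapter` encoder kind (any callable producing N×d features);
nothing in the package depends on them. All training-time computation
runs on a small reverse-mode autodiff core (`dermalign.autodiff`,
float64, finite-difference-verified in the test suite).

## Objective

Five weighted terms: image and text cross-entropy through the shared
head, mean elementwise L1 between paired embeddings, mean (1 − cosine)
between paired embeddings, and a contrastive term — NT-Xent (2N-view:
both modalities stacked, positives are the cross-modal pairs, negatives
are all other rows intra- and cross-modality) or InfoNCE (symmetric
cross-modal only). Both use cosine similarity. Defaults: all weights 1,
except the contrastive weight (0.5 at temperature 0.5 for NT-Xent; 0.25
at temperature 0.07 for InfoNCE). L1 reduces by mean over all N×d
entries so its scale is comparable across embedding widths. Unimodal
training zeroes every text-side weight; the text branch is then never
evaluated and its parameters provably receive no updates.

**Alignment space.** The L1 / cosine / contrastive terms act on the
*encoder outputs* (pre-projection), not on the projection output. This
was a genuinely open design point; both variants were implemented and
measured on synthetic cohorts. Post-projection alignment couples the
classifier's input space directly to record-specific text variation
(descriptor wording, report turnover), and in that variant the
multimodal runs frequently scored *below* the unimodal baseline.
Aligning the encoder outputs leaves the shared head free to shape its
own classification space on top of the aligned features and restored a
non-negative multimodal gain for both contrastive presets across all
cohort seeds tested. Silhouette evaluation uses the same alignment-space
image embeddings, for consistency.

## Training protocol

Reference defaults (`TrainConfig()`): 10 epochs, Adam, learning rate
1e-4, batch size 32, weight decay 1e-5, report turnover probability 0.5.
These assume gently-refined pretrained backbones. The from-scratch
reference encoders need more optimization, so `TrainConfig.desk_scale()`
raises the learning rate to 3e-3 and the epoch count to 30, keeping
everything else; this is the configuration used in the examples, the
co-learning tests and the acceptance script.

Class balancing is weighted sampling with replacement (epoch length =
training-partition size): each record's weight is the reciprocal of its
class count, so every class is drawn with probability 1/5. Image
augmentation composes one right-angle rotation ({0°, 90°, 180°, 270°};
right angles avoid interpolation artifacts on small images), optional
horizontal/vertical flips, and a per-channel uniform RGB shift bounded
at 5% of dynamic range (capped at 10% — "light"). Model selection keeps
the epoch with minimum validation image cross-entropy (first epoch wins
ties); validation deliberately ignores every text-side loss because only
image performance is clinically relevant.

Reproducibility: a run is fully determined by the data, the encoder
`init_seed`s and `TrainConfig.seed`, which drives one `numpy`
Generator for sampling, augmentation and turnover.

## Synthetic cohorts

`generate_cohort` emulates a curated paired cohort: each class is a
parametric motif on a skin-tone background — ellipse (NEV), ragged
star polygon (MEL), annulus (BCC), stippled patch (ACK), scaly checker
patch (BEK) — with a class base color, geometry jitter, per-image color
jitter, and additive Gaussian pixel noise (`noise_sd`, fraction of the
8-bit range). `motif_separation` interpolates the five base colors
between their common mean (0) and the full palette (1).

Defaults (`n_per_class=40`, `image_size=64`, `noise_sd=0.15`,
`motif_separation=0.45`, `subclass_rate=0.3`) were chosen to put the
*image-only* task in a moderately difficult regime — the hand-written
color-rule oracle scores well below 1 but far above chance — leaving
headroom for text-side information to matter, as in the agreement range
reference protocols report on real multi-source cohorts. A
nearest-palette-color rule with background subtraction
(`rule_based_classify`) certifies that class signal exists (accuracy 1.0
at zero noise and full separation) and degrades monotonically with
noise.

Reports are produced by the deterministic template synthesizer with a
**class-conditioned descriptor profile**: each class has typical options
per descriptor field (e.g. arborizing vessels for BCC, asymmetry and
dark colors for MEL), drawn with probability 0.8, any option otherwise.
This emulates a report writer who knows the diagnosis metadata, making
descriptor fields class-discriminative — the property the co-learning
mechanism needs. With class-*independent* (uniform) descriptors, which
the bare synthesizer op still provides by default, the alignment losses
force the image branch to fit record-specific text noise and the
multimodal benefit measurably disappears. All choices remain inside the
closed vocabulary regardless of profile.

What the cohorts do **not** emulate: photorealistic lesion morphology,
skin-tone distribution shift, acquisition artifacts (rulers, hairs),
source heterogeneity (a single synthetic "source"), and free-text report
style. Passing tests therefore show that the *mechanism* behaves as
described under controlled signal, not that the pipeline reaches any
particular accuracy on real dermatology data.

## Evaluation protocol

Cohen's κ = (p_o − p_e)/(1 − p_e) per test source (never pooled across
sources), with the convention κ = 1 when both vectors are constant and
equal. Silhouette uses Euclidean distance on alignment-space image
embeddings; singleton clusters and a = b = 0 contribute s(i) = 0.
Repetitions re-initialize encoders and head from consecutive seeds; sd
uses the n−1 denominator. The Wilcoxon signed-rank test is two-sided,
drops zero differences, enumerates the exact 2^n null (midranks for
ties) for n ≤ 12 and uses the tie-corrected normal approximation above;
all-zero differences return p = 1 with a warning. Setup comparisons pair
the per-seed κ values.

## Numerical choices and degenerate inputs

* Contrastive losses subtract a detached per-anchor maximum before
  exponentiation (stable log-sum-exp); N = 1 yields exactly 0 for both.
* Zero-norm embedding rows are an error for cosine-based losses.
* `normalize_label` resolves codes/display names/aliases first and
  consults the subclass map only as fallback; matching is case- and
  whitespace-insensitive.
* Stratified splitting floors the training and validation shares per
  class and assigns the remainder to testing, so partitions are disjoint
  and exhaustive for any fractions summing to 1.
* Adam applies weight decay as an L2 term on the gradient.

## Known limitations

* The multimodal gain at desk scale is small relative to its seed-level
  variability: NT-Xent in particular can fall below the unimodal mean on
  individual cohort draws (the acceptance script reports whatever it
  measures), and under substantially harder conditions (separation
  ~0.35, noise ~0.2) both presets lose their advantage. Averaging over
  cohort replicates, InfoNCE's gain was consistently positive in our
  runs; NT-Xent's hovered near zero. This mirrors the high run-to-run
  variability such protocols report.
* The from-scratch text branch and the 2N NT-Xent formulation interact
  badly with near-duplicate in-batch reports (same class and rendition):
  identical rows become maximally-similar negatives. Real heterogeneous
  report corpora make this collision rare; the synthetic cohort does
  not.
* The image encoder requires spatial sizes divisible by 16 and the text
  featurizer ignores word order entirely.
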