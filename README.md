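# dermalign

Multimodal co-learning for skin-lesion classification: transfer
class-discriminative information from clinical report text into an image
representation, so that **image-only inference** improves.

## The problem

Public dermatology datasets (dermoscopic and clinical photographs of
lesions over classes such as benign keratosis, benign nevus, actinic
keratosis, basal-cell cancer and melanoma) are plentiful but almost never
ship paired diagnostic reports, which blocks multimodal training. The
strategy implemented here sidesteps that: reports are **synthesized from
the image metadata** (class, optional subclass) under a closed descriptor
vocabulary, paired with the images, and used only at training time. The
package is for researchers who want to study this co-learning recipe
end-to-end at desk scale — synthetic cohorts, small reference encoders,
full evaluation protocol — without GPU-scale backbones or external data.

## The model

Two branches produce width-`d` embeddings: an image encoder `f_img` (a
small strided CNN) and a text encoder `f_txt` (token-hash bag-of-words +
linear). A **shared head** — one linear projection and one classifier
serving both modalities — maps either embedding to 5 class logits.
Training minimizes the composite objective

```
L = w_img·CE(img) + w_txt·CE(txt) + w_L1·L1(z_img, z_txt)
    + w_cos·(1 − cos(z_img, z_txt)) + w_ssl·L_SSL(z_img, z_txt)
```

where `z` are the encoder outputs for paired records, `CE` is
cross-entropy through the shared head, and `L_SSL` is a contrastive term:
**NT-Xent** (2N-view, cosine similarities, temperature 0.5, weight 0.5)
or **InfoNCE** (symmetric cross-modal, temperature 0.07, weight 0.25);
all other weights are 1. Class imbalance is handled by inverse-frequency
sampling; images are augmented with right-angle rotations, flips and
light RGB jitter, and reports by random *turnover* between the structured
and the synthesized rendition. Validation and model selection use image
cross-entropy only, and the test partition is images only.

Evaluation follows the repeated-seed protocol: Cohen's κ per test source
and the silhouette score of the image embeddings under the class labels,
reported as mean ± sd over independent repetitions, with paired two-sided
Wilcoxon signed-rank tests between training setups.

## Worked example

`examples/04_evaluation_protocol.py` trains the unimodal baseline and
both multimodal setups five times each on a synthetic cohort
(5 classes × 40 images, 64×64, moderate noise) and prints:

```
unimodal      kappa 0.911±0.107   silhouette 0.457±0.045
MM (NT-Xent)  kappa 0.946±0.038   silhouette 0.461±0.061
MM (InfoNCE)  kappa 0.968±0.032   silhouette 0.518±0.022

kappa, mean±sd over 5 seeds (*: paired Wilcoxon p < 0.05 vs unimodal):
| Dataset | unimodal | MM (NT-Xent) | MM (InfoNCE) |
|---|---|---|---|
| synthetic | 0.911±0.107 | 0.946±0.038 | 0.968±0.032 |
```

Reading: κ is chance-corrected agreement between predicted and true
classes on the held-out, image-only test records; both multimodal setups
raise the mean κ over the image-only baseline — text used during
training improved image-only inference — and InfoNCE also tightens the
embedding clusters (higher silhouette). The other examples demonstrate
cohort generation (`01`), report synthesis and turnover (`02`) and a
single training run (`03`).

A thin CLI mirrors the library for shell use:

```bash
dermalign synth --n-per-class 40 --seed 1 --out cohort/
dermalign report-gen --manifest cohort/manifest.csv --seed 1 --out reports.jsonl
dermalign train --config exp.yaml --mode multimodal --out run/
dermalign eval --run-dir run/ --manifest cohort/manifest.csv --out metrics.json
dermalign repeat --config exp.yaml --n-runs 10 --out mm.json
dermalign compare --runs mm.json uni.json --out table.md
```

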