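"""Evaluation protocol: Cohen's kappa, silhouette, repeats, Wilcoxon.

Image-only test performance is summarized by Cohen's kappa per test
source; embedding quality by the silhouette score of the post-projection
image embeddings under the true class labels. Experiments are repeated
over independent seeds and reported as mean +/- sample sd; paired
two-sided Wilcoxon signed-rank tests compare training setups on their
per-seed kappa values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata, wilcoxon as _scipy_wilcoxon

from .core_types import DatasetManifest, LesionClass
from .encoders import EncoderSpec, SharedHead, build_encoder
from .report_synthesis import ReportPair
from .training import TrainConfig, TrainedModel, load_record_image, predict_images, train

__all__ = [
    "MetricReport",
    "RepeatResult",
    "cohen_kappa",
    "silhouette",
    "wilcoxon_signed_rank",
    "repeat_experiment",
    "comparison_table",
]


@dataclass
class MetricReport:
    """Per-run values of one metric with their mean +/- sample sd."""

    per_run_values: list[float]
    mean: float
    sd: float
    wilcoxon_p: Optional[float] = None

    @classmethod
    def from_values(
        cls, values: Sequence[float], wilcoxon_p: Optional[float] = None
    ) -> "MetricReport":
        v = [float(x) for x in values]
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        return cls(per_run_values=v, mean=float(np.mean(v)), sd=sd,
                   wilcoxon_p=wilcoxon_p)

    def __str__(self) -> str:
        star = "*" if self.wilcoxon_p is not None and self.wilcoxon_p < 0.05 else ""
        return f"{self.mean:.3f}±{self.sd:.3f}{star}"


def _to_codes(labels: Sequence) -> np.ndarray:
    return np.array(
        [l.index if isinstance(l, LesionClass) else int(l) for l in labels]
    )


def cohen_kappa(y_true: Sequence, y_pred: Sequence) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement fraction and p_e the expected agreement
    of independent raters with the observed marginals. When both vectors
    are constant and equal (p_e = 1, p_o = 1) the score is 1 by
    convention.
    """
    t, p = _to_codes(y_true), _to_codes(y_pred)
    if len(t) != len(p):
        raise ValueError("y_true and y_pred must have equal length")
    if len(t) == 0:
        raise ValueError("need at least one sample")
    n = len(t)
    p_o = float(np.mean(t == p))
    classes = np.union1d(t, p)
    p_e = sum(
        float(np.mean(t == c)) * float(np.mean(p == c)) for c in classes
    )
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def silhouette(
    embeddings: np.ndarray, labels: Sequence, distance: str = "euclidean"
) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b) under the class labels.

    a(i): mean distance to same-cluster points (excluding self); b(i):
    minimum over other clusters of the mean distance to that cluster.
    Samples in singleton clusters, and samples with a = b = 0, contribute
    s(i) = 0.
    """
    x = np.asarray(embeddings, dtype=float)
    lab = _to_codes(labels)
    if x.ndim != 2 or x.shape[0] != len(lab):
        raise ValueError("embeddings must be N x d with one label per row")
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct labels")
    dist = cdist(x, x, metric=distance)
    scores = np.zeros(len(lab))
    for i in range(len(lab)):
        same = lab == lab[i]
        n_same = same.sum()
        if n_same <= 1:
            continue  # singleton cluster: s(i) = 0
        a = dist[i, same].sum() / (n_same - 1)
        b = min(
            dist[i, lab == c].mean() for c in uniq if c != lab[i]
        )
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(scores.mean())


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> float:
    """Paired two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped. The null distribution is enumerated
    exactly over all 2^n sign assignments (midranks for ties) for n <= 12;
    larger samples use the normal approximation with tie correction. If
    every difference is zero, p = 1 is returned with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 12:
        # exact two-sided tail over all sign assignments
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        dist = signs @ ranks
        total = len(dist)
        p_le = np.sum(dist <= w_plus + 1e-12) / total
        p_ge = np.sum(dist >= w_plus - 1e-12) / total
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    res = _scipy_wilcoxon(a, b, zero_method="wilcox", method="approx",
                          correction=False)
    return float(res.pvalue)


@dataclass
class RepeatResult:
    """Per-source metric reports over repeated training runs."""

    kappa: dict[str, MetricReport]
    silhouette: dict[str, MetricReport]
    seeds: list[int] = field(default_factory=list)


def _per_source_test_records(manifest: DatasetManifest):
    by_source: dict[str, list] = {}
    for r in manifest.partition_records("testing"):
        by_source.setdefault(r.source, []).append(r)
    return by_source


def repeat_experiment(
    manifest: DatasetManifest,
    reports: Optional[Mapping[str, ReportPair]],
    image_spec: EncoderSpec,
    text_spec: EncoderSpec,
    cfg: TrainConfig,
    n_runs: int = 10,
    base_seed: int = 0,
    head_width: int = 16,
    base_dir=None,
) -> RepeatResult:
    """Train ``n_runs`` independent models (seeds base_seed .. +n_runs-1)
    and report per-test-source kappa and silhouette as mean +/- sd.

    Each run re-initializes the encoders and head from its seed, so the
    repeats are genuinely independent repetitions of the same setup.
    Kappa is computed per test source, never pooled across sources;
    silhouette uses the alignment-space image embeddings of each source's
    test records.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    by_source = _per_source_test_records(manifest)
    if not by_source:
        raise ValueError("testing partition is empty")
    test_images = {
        src: np.stack([load_record_image(r, base_dir) for r in recs])
        for src, recs in by_source.items()
    }
    test_labels = {
        src: [r.label for r in recs] for src, recs in by_source.items()
    }

    kappas: dict[str, list[float]] = {s: [] for s in by_source}
    sils: dict[str, list[float]] = {s: [] for s in by_source}
    seeds = list(range(base_seed, base_seed + n_runs))
    for seed in seeds:
        img_enc = build_encoder(replace(image_spec, init_seed=seed))
        txt_enc = build_encoder(replace(text_spec, init_seed=seed))
        head = SharedHead(image_spec.d, h=head_width, init_seed=seed)
        run_cfg = replace(cfg, seed=seed)
        model, _ = train(
            manifest, reports, (img_enc, txt_enc), head, run_cfg, base_dir
        )
        for src in by_source:
            preds = predict_images(model, test_images[src])
            kappas[src].append(cohen_kappa(test_labels[src], preds))
            emb = model.embed_images(test_images[src])
            if len(set(l.code for l in test_labels[src])) >= 2:
                sils[src].append(silhouette(emb, test_labels[src]))
    return RepeatResult(
        kappa={s: MetricReport.from_values(v) for s, v in kappas.items()},
        silhouette={
            s: MetricReport.from_values(v) for s, v in sils.items() if v
        },
        seeds=seeds,
    )


def comparison_table(
    results: Mapping[str, RepeatResult],
    baseline: str,
    metric: str = "kappa",
) -> str:
    """Markdown table of mean +/- sd per source and setup.

    Setups other than ``baseline`` get a star when the paired two-sided
    Wilcoxon test of their per-seed values against the baseline's is
    significant at 0.05.
    """
    names = list(results)
    if baseline not in names:
        raise KeyError(f"baseline {baseline!r} not among results")
    sources = sorted(getattr(results[baseline], metric))
    lines = [
        "| Dataset | " + " | ".join(names) + " |",
        "|" + "---|" * (len(names) + 1),
    ]
    for src in sources:
        cells = []
        for name in names:
            rep = getattr(results[name], metric)[src]
            star = ""
            if name != baseline:
                base_vals = getattr(results[baseline], metric)[src].per_run_values
                if len(base_vals) == len(rep.per_run_values):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p = wilcoxon_signed_rank(rep.per_run_values, base_vals)
                    if p < 0.05:
                        star = "*"
            cells.append(f"{rep.mean:.3f}±{rep.sd:.3f}{star}")
        lines.append(f"| {src} | " + " | ".join(cells) + " |")
    return "\n".join(lines)
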