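"""Metrics against independent oracles (sklearn, explicit loops,
exhaustive enumeration)."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn.metrics import cohen_kappa_score, silhouette_score

from dermalign import (
    EncoderSpec,
    LossWeights,
    MetricReport,
    cohen_kappa,
    repeat_experiment,
    silhouette,
    wilcoxon_signed_rank,
)
from dermalign.training import TrainConfig

rng = np.random.default_rng(99)


# ---------------------------------------------------------------- oracles
def kappa_oracle(y_true, y_pred):
    """Direct confusion-matrix tally."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    n = len(y_true)
    classes = sorted(set(y_true) | set(y_pred))
    cm = np.zeros((len(classes), len(classes)))
    for t, p in zip(y_true, y_pred):
        cm[classes.index(t), classes.index(p)] += 1
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    return (p_o - p_e) / (1 - p_e)


def silhouette_oracle(x, labels):
    """Explicit double loop over samples and clusters."""
    x, labels = np.asarray(x, float), np.asarray(labels)
    n = len(x)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(x[i] - x[j]) for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(scores))


def wilcoxon_oracle(a, b):
    """Exhaustive 2^n two-sided enumeration with midranks."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    dist = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    p_le = sum(x <= w + 1e-12 for x in dist) / len(dist)
    p_ge = sum(x >= w - 1e-12 for x in dist) / len(dist)
    return min(1.0, 2 * min(p_le, p_ge))


# ------------------------------------------------------------------ kappa
class TestCohenKappa:
    def test_perfect_agreement(self):
        y = [0, 1, 2, 3, 4, 0, 1]
        assert cohen_kappa(y, y) == 1.0

    def test_chance_level(self):
        assert cohen_kappa([0, 0, 1, 1], [0, 0, 0, 0]) == 0.0

    def test_matches_oracles_on_random_instances(self):
        r = np.random.default_rng(3)
        for _ in range(100):
            t = r.integers(0, 5, size=50)
            p = r.integers(0, 5, size=50)
            ours = cohen_kappa(t, p)
            assert ours == pytest.approx(kappa_oracle(t, p), abs=1e-10)
            assert ours == pytest.approx(cohen_kappa_score(t, p), abs=1e-10)

    def test_relabeling_invariance(self):
        t = rng.integers(0, 5, size=40)
        p = rng.integers(0, 5, size=40)
        perm = np.array([3, 0, 4, 1, 2])
        assert cohen_kappa(perm[t], perm[p]) == pytest.approx(
            cohen_kappa(t, p), abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([0, 1], [0])


# ------------------------------------------------------------- silhouette
class TestSilhouette:
    def test_perfectly_separated_1d(self):
        x = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert silhouette(x, [0, 0, 1, 1]) == 1.0

    def test_all_identical_points(self):
        x = np.zeros((4, 2))
        assert silhouette(x, [0, 0, 1, 1]) == 0.0

    def test_matches_oracles_on_random_instances(self):
        r = np.random.default_rng(4)
        for _ in range(100):
            x = r.normal(size=(20, 3))
            labels = r.integers(0, 3, size=20)
            if len(set(labels.tolist())) < 2:
                continue
            ours = silhouette(x, labels)
            assert ours == pytest.approx(silhouette_oracle(x, labels), abs=1e-10)
            if min(np.bincount(labels)) >= 1:
                assert ours == pytest.approx(
                    silhouette_score(x, labels), abs=1e-10
                )

    def test_translation_and_scale_invariance(self):
        x = rng.normal(size=(15, 4))
        labels = rng.integers(0, 3, size=15)
        assert silhouette(3.7 * x + 11.0, labels) == pytest.approx(
            silhouette(x, labels), abs=1e-9
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((3, 2)), [1, 1, 1])


# --------------------------------------------------------------- wilcoxon
class TestWilcoxon:
    def test_no_signal(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_five_positive_distinct(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [0.5, 1.0, 2.0, 3.0, 4.5]
        assert wilcoxon_signed_rank(a, b) == pytest.approx(0.0625)

    def test_matches_enumeration_n10(self):
        r = np.random.default_rng(6)
        for _ in range(20):
            a = r.normal(size=10)
            b = r.normal(size=10)
            assert wilcoxon_signed_rank(a, b) == pytest.approx(
                wilcoxon_oracle(a, b), abs=1e-12
            )

    def test_large_n_approximation_reasonable(self):
        r = np.random.default_rng(8)
        a = r.normal(size=30)
        b = a + r.normal(0.8, 0.3, size=30)  # strong consistent shift
        assert wilcoxon_signed_rank(a, b) < 0.001


# ---------------------------------------------------------------- repeats
class TestRepeats:
    def test_two_point_formula(self):
        rep = MetricReport.from_values([0.5, 0.7])
        assert rep.mean == pytest.approx(0.6)
        assert rep.sd == pytest.approx(0.1414, abs=1e-4)

    def test_repeat_experiment_aggregation(self, small_cohort, small_manifest):
        cfg = TrainConfig.desk_scale(
            epochs=2, mode="unimodal", loss_weights=LossWeights.unimodal()
        )
        result = repeat_experiment(
            small_manifest,
            small_cohort.reports,
            EncoderSpec(kind="small_conv", d=8),
            EncoderSpec(kind="small_text", d=8),
            cfg,
            n_runs=2,
            base_seed=0,
            head_width=4,
        )
        rep = result.kappa["synthetic"]
        assert len(rep.per_run_values) == 2
        assert rep.mean == pytest.approx(np.mean(rep.per_run_values))
        assert rep.sd == pytest.approx(np.std(rep.per_run_values, ddof=1))
        assert "synthetic" in result.silhouette

    def test_n_runs_minimum(self, small_cohort, small_manifest):
        with pytest.raises(ValueError):
            repeat_experiment(
                small_manifest, small_cohort.reports,
                EncoderSpec(kind="small_conv", d=8),
                EncoderSpec(kind="small_text", d=8),
                TrainConfig(), n_runs=1,
            )
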