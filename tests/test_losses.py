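"""Loss components against independent brute-force oracles."""

import numpy as np
import pytest

from dermalign import (
    LossWeights,
    composite_loss,
    cosine_alignment,
    cross_entropy,
    info_nce,
    l1_alignment,
    nt_xent,
)

rng = np.random.default_rng(2024)


# ---------------------------------------------------------------- oracles
def ce_oracle(logits, labels):
    total = 0.0
    for row, lab in zip(logits, labels):
        p = np.exp(row) / np.exp(row).sum()
        total += -np.log(p[lab])
    return total / len(labels)


def cos_sim(u, v):
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def nt_xent_oracle(a, b, tau):
    """Explicit loop over all 2N anchors and their candidate sets."""
    rows = list(a) + list(b)
    n = len(a)
    total = 0.0
    for i, anchor in enumerate(rows):
        pos = i + n if i < n else i - n
        denom = sum(
            np.exp(cos_sim(anchor, rows[k]) / tau)
            for k in range(2 * n)
            if k != i
        )
        total += -np.log(np.exp(cos_sim(anchor, rows[pos]) / tau) / denom)
    return total / (2 * n)


def info_nce_oracle(a, b, tau):
    """Directional softmax loops, image->text then text->image."""
    n = len(a)

    def direction(anchors, candidates):
        total = 0.0
        for i in range(n):
            scores = [cos_sim(anchors[i], candidates[j]) / tau for j in range(n)]
            total += -np.log(np.exp(scores[i]) / np.sum(np.exp(scores)))
        return total / n

    return 0.5 * (direction(a, b) + direction(b, a))


# ----------------------------------------------------------- cross-entropy
class TestCrossEntropy:
    def test_uniform_logits(self):
        assert cross_entropy(np.zeros((3, 5)), [0, 3, 4]) == pytest.approx(np.log(5))

    def test_confident_limit(self):
        logits = np.full((2, 5), -1e4)
        logits[0, 1] = logits[1, 2] = 1e4
        assert cross_entropy(logits, [1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle(self):
        logits = rng.normal(size=(4, 5))
        labels = [0, 1, 2, 4]
        assert cross_entropy(logits, labels) == pytest.approx(
            ce_oracle(logits, labels), abs=1e-6
        )

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.zeros((1, 5)), [7])


# -------------------------------------------------------------- alignment
class TestL1Alignment:
    def test_identity_and_offset(self):
        e = rng.normal(size=(3, 4))
        assert l1_alignment(e, e) == 0.0
        assert l1_alignment(np.ones((2, 3)), np.zeros((2, 3))) == 1.0

    def test_matches_elementwise_oracle(self):
        a, b = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        assert l1_alignment(a, b) == pytest.approx(np.abs(a - b).mean(), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_alignment(np.ones((2, 3)), np.ones((3, 2)))


class TestCosineAlignment:
    def test_identical_antiparallel_orthogonal(self):
        e = rng.normal(size=(4, 3))
        assert cosine_alignment(e, e) == pytest.approx(0.0)
        assert cosine_alignment(e, -e) == pytest.approx(2.0)
        a = np.array([[1.0, 0.0], [0.0, 2.0]])
        b = np.array([[0.0, 3.0], [4.0, 0.0]])
        assert cosine_alignment(a, b) == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_alignment(np.zeros((1, 3)), np.ones((1, 3)))


# ------------------------------------------------------------ contrastive
class TestNTXent:
    def test_single_pair_is_zero(self):
        a, b = rng.normal(size=(1, 4)), rng.normal(size=(1, 4))
        assert nt_xent(a, b, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_two_pair_oracle(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        b = np.array([[1.0, 1.0], [-1.0, 1.0]])
        assert nt_xent(a, b, 0.5) == pytest.approx(
            nt_xent_oracle(a, b, 0.5), abs=1e-6
        )

    def test_scale_invariance(self):
        a, b = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
        assert nt_xent(10 * a, 10 * b, 0.5) == pytest.approx(
            nt_xent(a, b, 0.5), abs=1e-9
        )

    def test_pair_permutation_invariance(self):
        a, b = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        perm = [2, 0, 3, 1]
        assert nt_xent(a[perm], b[perm], 0.3) == pytest.approx(
            nt_xent(a, b, 0.3), abs=1e-9
        )

    def test_decreases_with_positive_similarity(self):
        # 2-pair instance; rotate text row 0 toward image row 0
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        losses = []
        for angle in (1.2, 0.8, 0.4, 0.1):
            b = np.array(
                [[np.cos(angle), np.sin(angle)], [-1.0, 1.0]]
            )
            losses.append(nt_xent(a, b, 0.5))
        assert all(x > y for x, y in zip(losses, losses[1:]))


class TestInfoNCE:
    def test_single_pair_is_zero(self):
        assert info_nce(rng.normal(size=(1, 3)), rng.normal(size=(1, 3))) == 0.0

    def test_three_pair_oracle(self):
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        assert info_nce(a, b, 0.07) == pytest.approx(
            info_nce_oracle(a, b, 0.07), abs=1e-6
        )

    def test_aligned_low_temperature_vanishes(self):
        a = rng.normal(size=(4, 6))
        assert info_nce(a, a.copy(), 0.01) == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("kind", ["nt_xent", "info_nce"])
def test_contrastive_oracle_equivalence_100_instances(kind):
    """Both SSL losses match explicit enumeration oracles to 1e-6 on 100
    random small instances (N <= 8, d <= 8)."""
    r = np.random.default_rng(7)
    fn, oracle = (
        (nt_xent, nt_xent_oracle) if kind == "nt_xent" else (info_nce, info_nce_oracle)
    )
    for _ in range(100):
        n = int(r.integers(1, 9))
        d = int(r.integers(2, 9))
        tau = float(r.uniform(0.07, 1.0))
        a, b = r.normal(size=(n, d)), r.normal(size=(n, d))
        assert fn(a, b, tau) == pytest.approx(oracle(a, b, tau), abs=1e-6)


# -------------------------------------------------------------- composite
class TestCompositeLoss:
    def test_preset_weighted_sums(self):
        """Hand-computed totals for component values (1, 1, 0.2, 0.1, 2)."""
        w_nt = LossWeights.nt_xent_default()
        total_nt = (w_nt.w_ce_image * 1 + w_nt.w_ce_text * 1 + w_nt.w_l1 * 0.2
                    + w_nt.w_cos * 0.1 + w_nt.w_ssl * 2)
        assert total_nt == pytest.approx(3.3, abs=1e-9)
        assert (w_nt.tau, w_nt.w_ssl) == (0.5, 0.5)
        w_in = LossWeights.info_nce_default()
        total_in = (w_in.w_ce_image * 1 + w_in.w_ce_text * 1 + w_in.w_l1 * 0.2
                    + w_in.w_cos * 0.1 + w_in.w_ssl * 2)
        assert total_in == pytest.approx(2.8, abs=1e-9)
        assert (w_in.tau, w_in.w_ssl) == (0.07, 0.25)

    @pytest.mark.parametrize(
        "weights",
        [LossWeights.nt_xent_default(), LossWeights.info_nce_default()],
    )
    def test_total_reproducible_from_breakdown(self, weights):
        n, d = 6, 8
        li, lt = rng.normal(size=(n, 5)), rng.normal(size=(n, 5))
        ei, et = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        labels = [i % 5 for i in range(n)]
        bd = composite_loss(li, lt, labels, ei, et, weights)
        manual = (
            weights.w_ce_image * bd.ce_image
            + weights.w_ce_text * bd.ce_text
            + weights.w_l1 * bd.l1
            + weights.w_cos * bd.cosine
            + weights.w_ssl * bd.ssl
        )
        assert bd.total == pytest.approx(manual, abs=1e-6)
        assert all(
            v >= 0 for v in (bd.ce_image, bd.ce_text, bd.l1, bd.cosine, bd.ssl)
        )

    def test_all_weights_zero(self):
        w = LossWeights(w_ce_image=0, w_ce_text=0, w_l1=0, w_cos=0, w_ssl=0)
        bd = composite_loss(
            rng.normal(size=(3, 5)), rng.normal(size=(3, 5)), [0, 1, 2],
            rng.normal(size=(3, 4)), rng.normal(size=(3, 4)), w,
        )
        assert bd.total == 0.0

    def test_unimodal_preset_skips_text(self):
        w = LossWeights.unimodal()
        bd = composite_loss(rng.normal(size=(3, 5)), None, [0, 1, 2], None, None, w)
        assert bd.ce_text == bd.l1 == bd.cosine == bd.ssl == 0.0
        assert bd.total == pytest.approx(bd.ce_image)
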