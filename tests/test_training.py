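import numpy as np
import pytest

from dermalign import (
    EncoderSpec,
    LesionClass,
    LossWeights,
    SharedHead,
    build_encoder,
    cohen_kappa,
    generate_cohort,
    predict_images,
    split_cohort,
    train,
)
from dermalign.synthetic_data import SynthConfig
from dermalign.training import AugmentConfig, TrainConfig, augment_image, balanced_sampler


def build_models(d=16, h=8, seed=0):
    img = build_encoder(EncoderSpec(kind="small_conv", d=d, init_seed=seed))
    txt = build_encoder(EncoderSpec(kind="small_text", d=d, init_seed=seed))
    return img, txt, SharedHead(d, h, init_seed=seed)


class TestBalancedSampler:
    def test_balanced_classes_reduce_to_uniform(self, small_manifest, rng):
        sampler = balanced_sampler(small_manifest, "training", rng)
        ids = [next(sampler) for _ in range(2000)]
        by_id = {r.record_id: r for r in small_manifest.partition_records("training")}
        counts = np.bincount(
            [by_id[i].label.index for i in ids], minlength=5
        ) / len(ids)
        np.testing.assert_allclose(counts, 0.2, atol=0.04)

    def test_unbalanced_classes_drawn_uniformly(self, rng):
        from dermalign import aggregate_manifest
        from conftest import make_record

        records = []
        sizes = {LesionClass.BEK: 100, LesionClass.NEV: 10,
                 LesionClass.ACK: 10, LesionClass.BCC: 10, LesionClass.MEL: 10}
        for cls, n in sizes.items():
            for i in range(n):
                records.append(make_record(rid=f"{cls.code}{i}", cls=cls))
        manifest = aggregate_manifest(records)
        sampler = balanced_sampler(manifest, "training", rng)
        draws = [next(sampler) for _ in range(10_000)]
        frac_nev = np.mean([d.startswith("NEV") for d in draws])
        assert 0.17 <= frac_nev <= 0.23  # binomial bound around 1/5

    def test_study_training_counts_weighted_by_reciprocals(self):
        """Inverse-frequency weighting on the published training counts
        (1465, 4706, 569, 2423, 2489) makes per-draw class probability
        uniform over the five classes."""
        from dermalign import study_manifest

        manifest = study_manifest()
        r = np.random.default_rng(1)
        sampler = balanced_sampler(manifest, "training", r)
        by_id = {rec.record_id: rec for rec in manifest.partition_records("training")}
        draws = [by_id[next(sampler)].label.index for _ in range(10_000)]
        freq = np.bincount(draws, minlength=5) / len(draws)
        np.testing.assert_allclose(freq, 0.2, atol=0.02)

    def test_empty_class_rejected(self, rng):
        from dermalign import aggregate_manifest
        from conftest import make_record

        manifest = aggregate_manifest(
            [make_record(rid="a", cls=LesionClass.MEL)]
        )
        with pytest.raises(ValueError, match="zero records"):
            next(balanced_sampler(manifest, "training", rng))


class TestAugmentImage:
    def test_disabled_is_identity(self, rng):
        img = np.random.default_rng(0).integers(0, 256, (16, 16, 3)).astype(np.uint8)
        out = augment_image(img, AugmentConfig.disabled(), rng)
        np.testing.assert_array_equal(out, img)

    def test_forced_rotation_preserves_pixel_multiset(self, rng):
        img = np.random.default_rng(1).integers(0, 256, (16, 16, 3)).astype(np.uint8)
        cfg = AugmentConfig(rotation_angles=(90,), hflip=False, vflip=False,
                            rgb_jitter_magnitude=0.0)
        out = augment_image(img, cfg, rng)
        np.testing.assert_array_equal(out, np.rot90(img))
        assert sorted(out.flatten()) == sorted(img.flatten())

    def test_flips_are_involutions(self, rng):
        img = np.random.default_rng(2).integers(0, 256, (16, 16, 3)).astype(np.uint8)
        np.testing.assert_array_equal(np.fliplr(np.fliplr(img)), img)
        cfg = AugmentConfig(rotation_angles=(0,), hflip=True, vflip=True,
                            rgb_jitter_magnitude=0.0)
        out = augment_image(img, cfg, rng)
        assert sorted(out.flatten()) == sorted(img.flatten())

    def test_jitter_bounded(self, rng):
        img = np.full((16, 16, 3), 128, dtype=np.uint8)
        cfg = AugmentConfig(rotation_angles=(0,), hflip=False, vflip=False,
                            rgb_jitter_magnitude=0.1)
        out = augment_image(img, cfg, rng)
        assert np.abs(out.astype(int) - 128).max() <= 26  # 0.1 * 255 + rounding

    def test_heavy_jitter_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(rgb_jitter_magnitude=0.5)

    def test_non_right_angle_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(rotation_angles=(45,))


class TestTrain:
    def test_zero_epochs_noop(self, small_cohort, small_manifest):
        img, txt, head = build_models()
        before = {k: v.copy() for k, v in img.state_dict().items()}
        cfg = TrainConfig(epochs=0)
        _, history = train(
            small_manifest, small_cohort.reports, (img, txt), head, cfg
        )
        assert history.epochs == []
        for k, v in img.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_deterministic_given_seed(self, small_cohort, small_manifest):
        outs = []
        for _ in range(2):
            img, txt, head = build_models(seed=3)
            cfg = TrainConfig.desk_scale(epochs=2, seed=11)
            model, history = train(
                small_manifest, small_cohort.reports, (img, txt), head, cfg
            )
            test = small_manifest.partition_records("testing")
            preds = predict_images(model, np.stack([r.image for r in test]))
            outs.append((history.to_dict(), [p.code for p in preds]))
        assert outs[0] == outs[1]

    def test_unimodal_text_untouched(self, small_cohort, small_manifest):
        img, txt, head = build_models()
        before = {k: v.copy() for k, v in txt.state_dict().items()}
        cfg = TrainConfig.desk_scale(epochs=2, mode="unimodal",
                                     loss_weights=LossWeights.unimodal())
        train(small_manifest, None, (img, txt), head, cfg)
        for k, v in txt.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_multimodal_requires_reports(self, small_manifest):
        img, txt, head = build_models()
        with pytest.raises(ValueError, match="reports"):
            train(small_manifest, None, (img, txt), head,
                  TrainConfig(epochs=1))

    def test_selected_epoch_minimizes_val_ce(self, small_cohort, small_manifest):
        img, txt, head = build_models(seed=1)
        cfg = TrainConfig.desk_scale(epochs=4, seed=5)
        _, history = train(
            small_manifest, small_cohort.reports, (img, txt), head, cfg
        )
        ces = [e.val_ce for e in history.epochs]
        assert history.selected_epoch == int(np.argmin(ces))

    def test_separable_cohort_unimodal_kappa(self):
        """With noiseless rendering the image branch alone reaches
        near-perfect held-out agreement (kappa >= 0.9)."""
        cohort = generate_cohort(SynthConfig(n_per_class=30, noise_sd=0.0, seed=17))
        manifest = split_cohort(cohort, (0.6, 0.2, 0.2), seed=17)
        img = build_encoder(EncoderSpec(kind="small_conv", d=32, init_seed=0))
        txt = build_encoder(EncoderSpec(kind="small_text", d=32, init_seed=0))
        head = SharedHead(32, 16, init_seed=0)
        cfg = TrainConfig.desk_scale(mode="unimodal",
                                     loss_weights=LossWeights.unimodal(), seed=0)
        model, _ = train(manifest, None, (img, txt), head, cfg)
        test = manifest.partition_records("testing")
        preds = predict_images(model, np.stack([r.image for r in test]))
        assert cohen_kappa([r.label for r in test], preds) >= 0.9


@pytest.fixture(scope="module")
def trained(small_cohort, small_manifest):
    img, txt, head = build_models(seed=2)
    cfg = TrainConfig.desk_scale(epochs=2, seed=2)
    model, _ = train(
        small_manifest, small_cohort.reports, (img, txt), head, cfg
    )
    return model


class TestPredictImages:
    def test_empty_batch(self, trained):
        assert predict_images(trained, []) == []

    def test_duplicated_image_duplicated_prediction(self, trained, small_cohort):
        img = small_cohort.records[0].image
        preds = predict_images(trained, np.stack([img, img]))
        assert preds[0] is preds[1]

    def test_batching_invariance(self, trained, small_cohort):
        imgs = np.stack([r.image for r in small_cohort.records[:10]])
        whole = predict_images(trained, imgs)
        parts = predict_images(trained, imgs[:4]) + predict_images(trained, imgs[4:])
        assert whole == parts
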