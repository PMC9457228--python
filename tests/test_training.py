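"""Slice exclusion, schedules, augmentation and the two training steps."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from autoaspects.model import ModelConfig, build_model, build_slice_head
from autoaspects.training import (RegionAnnotation, SliceAnnotation, TrainConfig,
                                  apply_inplane_transform, augment,
                                  build_pretrain_set, finetune, inplane_matrix,
                                  lr_schedule, pretrain, sample_augmentation)


def _ann(sub, idx, hemi, label):
    return SliceAnnotation(subject_id=sub, slice_index=idx, hemisphere=hemi, label=label)


class TestBuildPretrainSet:
    def test_ipsilateral_normals_dropped(self):
        anns = [_ann("s1", 10, "left", "lesion"),
                _ann("s1", 8, "left", "normal"), _ann("s1", 9, "left", "normal"),
                _ann("s1", 8, "right", "normal"), _ann("s1", 9, "right", "normal"),
                _ann("s1", 10, "right", "normal")]
        kept = build_pretrain_set(anns)
        assert _ann("s1", 10, "left", "lesion") in kept
        assert all(a.hemisphere == "right" for a in kept if a.label == "normal")
        assert len(kept) == 4

    def test_lesion_free_subject_fully_retained(self):
        anns = [_ann("s2", i, h, "normal") for i in range(5) for h in ("left", "right")]
        assert build_pretrain_set(anns) == anns

    def test_bilateral_lesions_keep_only_lesion_slices(self):
        anns = [_ann("s3", 0, "left", "lesion"), _ann("s3", 1, "right", "lesion"),
                _ann("s3", 2, "left", "normal"), _ann("s3", 2, "right", "normal")]
        kept = build_pretrain_set(anns)
        assert all(a.label == "lesion" for a in kept) and len(kept) == 2

    def test_exhaustive_label_patterns(self):
        # enumerate all lesion/normal patterns over 2 hemispheres x 3 slices
        for pattern in itertools.product(["lesion", "normal"], repeat=6):
            anns = [_ann("s", i, h, lab)
                    for (i, h), lab in zip(itertools.product(range(3), ("left", "right")),
                                           pattern)]
            kept = set(build_pretrain_set(anns))
            lesioned_hemis = {a.hemisphere for a in anns if a.label == "lesion"}
            for a in anns:
                if a.label == "lesion":
                    assert a in kept          # never drops a lesion slice
                elif a.hemisphere in lesioned_hemis:
                    assert a not in kept      # never keeps ipsilateral normal
                else:
                    assert a in kept

    def test_unknown_subject_rejected(self):
        with pytest.raises(ValueError, match="unknown subject"):
            build_pretrain_set([_ann("ghost", 0, "left", "normal")],
                               known_subjects={"s1"})


class TestLrSchedule:
    def test_closed_form(self):
        cfg = TrainConfig()
        assert lr_schedule(0, cfg) == pytest.approx(5e-4)
        assert lr_schedule(1, cfg) == pytest.approx(4.95e-4)
        assert lr_schedule(200, cfg) == pytest.approx(5e-4 * 0.99 ** 200, rel=1e-12)

    def test_strictly_decreasing(self):
        cfg = TrainConfig()
        lrs = [lr_schedule(e, cfg) for e in range(201)]
        assert all(a > b for a, b in zip(lrs, lrs[1:]))

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, TrainConfig())


class TestAugment:
    def test_zero_draws_is_identity(self, rng):
        vol = rng.random((12, 10, 4))
        params = {"scale": (1.0, 1.0), "rot_deg": 0.0, "trans_frac": (0.0, 0.0)}
        out = apply_inplane_transform(vol, params)
        assert np.allclose(out, vol, atol=1e-12)

    def test_same_transform_for_every_slice(self, rng):
        # per-slice oracle: transforming each slice separately must equal
        # the volume transform slice by slice
        vol = rng.random((14, 12, 5))
        params = sample_augmentation(rng, TrainConfig())
        out = apply_inplane_transform(vol, params)
        for z in range(vol.shape[2]):
            ref = apply_inplane_transform(vol[:, :, z][..., None], params)[..., 0]
            assert np.allclose(out[:, :, z], ref, atol=1e-12)

    def test_output_dims_and_range_preserved(self, rng):
        vol = rng.random((9, 11, 3))
        out = augment(vol, rng)
        assert out.shape == vol.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_rotation_draws_uniform_within_range(self):
        rng = np.random.default_rng(2024)
        cfg = TrainConfig()
        draws = np.array([sample_augmentation(rng, cfg)["rot_deg"] for _ in range(10_000)])
        assert draws.min() >= -15.0 and draws.max() <= 15.0
        # KS against U(-15, 15)
        p = sps.kstest(draws, sps.uniform(loc=-15, scale=30).cdf).pvalue
        assert p > 0.01

    def test_no_through_plane_parameters_exist(self):
        cfg = TrainConfig()
        params = sample_augmentation(np.random.default_rng(0), cfg)
        assert set(params) == {"scale", "rot_deg", "trans_frac"}
        assert len(params["scale"]) == 2 and len(params["trans_frac"]) == 2

    def test_degenerate_single_pixel_passthrough(self):
        vol = np.full((1, 1, 3), 0.7)
        assert np.array_equal(augment(vol, np.random.default_rng(0)), vol)


def _toy_slices(n=40, seed=0):
    """Linearly separable 'bright vs dark' slices."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for i in range(n):
        y = i % 2
        base = 0.75 if y else 0.25
        xs.append(np.clip(base + 0.05 * rng.standard_normal((10, 10)), 0, 1))
        ys.append(y)
    return xs, np.array(ys)


class TestPretrain:
    def test_separable_toy_reaches_high_accuracy(self):
        xs, ys = _toy_slices()
        m = build_model(ModelConfig(seed=1))
        h = build_slice_head(m)
        log = pretrain(m, h, xs, ys, TrainConfig(epochs=50, batch_size=20, seed=1,
                                                 augment=False))
        assert log["accuracy"].iloc[-1] >= 0.95
        assert list(log.columns) == ["epoch", "lr", "loss", "accuracy"]

    def test_zero_epochs_leaves_weights_unchanged(self):
        xs, ys = _toy_slices(8)
        m = build_model()
        h = build_slice_head(m)
        before = {p.name: p.value.copy() for p in h.params()}
        pretrain(m, h, xs, ys, TrainConfig(epochs=0, seed=0))
        for p in h.params():
            assert np.array_equal(p.value, before[p.name])

    def test_fixed_seed_bit_identical_loss_curve(self):
        xs, ys = _toy_slices(16)
        logs = []
        for _ in range(2):
            m = build_model(ModelConfig(seed=5))
            h = build_slice_head(m)
            logs.append(pretrain(m, h, xs, ys, TrainConfig(epochs=3, batch_size=8, seed=5)))
        assert np.array_equal(logs[0]["loss"].to_numpy(), logs[1]["loss"].to_numpy())

    def test_single_class_refused_with_warning(self):
        xs, _ = _toy_slices(6)
        m = build_model()
        h = build_slice_head(m)
        with pytest.warns(UserWarning, match="single class"):
            with pytest.raises(ValueError, match="both classes"):
                pretrain(m, h, xs, np.ones(6), TrainConfig(epochs=1))


class TestFinetune:
    def test_zero_epochs_predictions_unchanged(self, rng):
        m = build_model(ModelConfig(seed=2))
        x = rng.random((3, 1, 10, 10, 4))
        before = m.forward(x)
        vols = [rng.random((10, 10, 4)) for _ in range(6)]
        finetune(m, vols, [0, 1, 0, 1, 0, 1], TrainConfig(epochs=0, seed=0))
        assert np.array_equal(m.forward(x), before)

    def test_cold_start_must_be_explicit(self):
        m = build_model()
        with pytest.raises(ValueError, match="cold_start"):
            finetune(m, [np.zeros((10, 10, 2))], [1], TrainConfig(epochs=1),
                     pretrained=False)

    def test_trained_model_monotone_in_hypodensity(self):
        # darkening inputs to a model trained to flag hypodense regions
        # must not decrease the mean predicted probability
        rng = np.random.default_rng(3)
        vols, ys = [], []
        for i in range(40):
            y = i % 2
            base = 0.5 - 0.25 * y  # label 1 = darker (hypodense)
            vols.append(np.clip(base + 0.05 * rng.standard_normal((10, 10, 3)), 0, 1))
            ys.append(y)
        m = build_model(ModelConfig(seed=6))
        finetune(m, vols, ys, TrainConfig(epochs=15, batch_size=10, seed=6),
                 cold_start=True, pretrained=False)
        test = [np.clip(0.5 + 0.05 * rng.standard_normal((10, 10, 3)), 0, 1)
                for _ in range(20)]
        p_base = np.mean([m.forward(v[None, None])[0] for v in test])
        p_dark = np.mean([m.forward(np.clip(v - 0.2, 0, 1)[None, None])[0]
                          for v in test])
        assert p_dark >= p_base - 0.02  # small statistical tolerance

    def test_annotation_csv_round_trip(self, tmp_path):
        import pandas as pd
        from autoaspects.training import (region_annotations_from_csv,
                                          slice_annotations_from_csv)
        sl = pd.DataFrame([{"subject_id": "s1", "slice_index": 4,
                            "hemisphere": "left", "label": "lesion"}])
        sl.to_csv(tmp_path / "slices.csv", index=False)
        anns = slice_annotations_from_csv(tmp_path / "slices.csv")
        assert anns == [SliceAnnotation("s1", 4, "left", "lesion")]
        rg = pd.DataFrame([{"subject_id": "s1", "region": "right_M3",
                            "label": "infarcted"}])
        rg.to_csv(tmp_path / "regions.csv", index=False)
        ranns = region_annotations_from_csv(tmp_path / "regions.csv")
        assert ranns[0].region.name == "M3" and ranns[0].region.hemisphere == "right"

    def test_loss_trend_nonincreasing(self):
        # trend check with a patience window, not strict monotonicity
        rng = np.random.default_rng(0)
        vols, ys = [], []
        for i in range(30):
            y = i % 2
            vols.append(np.clip(0.3 + 0.3 * y + 0.05 * rng.standard_normal((10, 10, 3)), 0, 1))
            ys.append(y)
        m = build_model(ModelConfig(seed=4))
        log = finetune(m, vols, ys, TrainConfig(epochs=12, batch_size=10, seed=4),
                       cold_start=True, pretrained=False)
        first = log["loss"].iloc[:4].mean()
        last = log["loss"].iloc[-4:].mean()
        assert last <= first
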