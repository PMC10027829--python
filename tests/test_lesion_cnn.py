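"""Lesion network: geometry contract, sampler statistics, backprop
correctness, tiled inference, conditioning."""

import numpy as np
import pytest
from scipy import stats

from petindex import PhantomSpec, generate_phantom
from petindex._unet import (UNet3D, output_size, softmax,
                            softmax_cross_entropy)
from petindex.lesion_cnn import (CnnConfig, LesionModel, SamplingError,
                                 encode_channels, predict_volume,
                                 sample_training_patches, tile_starts,
                                 train_model)


def tiny_cfg(**kw):
    """12³ -> 4³ contract, 4 channels: fast enough for unit tests."""
    base = dict(input_patch=(12, 12, 12), output_patch=(4, 4, 4), depth=1,
                convs_per_block=1, base_filters=4,
                regions=("bones", "joints"), working_spacing_mm=(3.0, 3.0, 3.0),
                epochs=2, patches_per_epoch=8, batch_size=4, seed=0)
    base.update(kw)
    return CnnConfig(**base)


@pytest.fixture(scope="module")
def tiny_case():
    return generate_phantom(PhantomSpec(shape=(24, 24, 24),
                                        spacing_mm=(3.0, 3.0, 3.0),
                                        n_lesions=1,
                                        lesion_radius_mm=(5.0, 7.0), seed=4))


class TestGeometry:
    def test_clinical_patch_contract_100_to_12(self):
        # depth 3, two 3x3x3 convolutions per block: 100 -> 12
        assert output_size(100, depth=3, convs_per_block=2) == 12

    def test_desk_patch_contract_36_to_12(self):
        assert output_size(36, depth=1, convs_per_block=3) == 12

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="yields output"):
            CnnConfig(input_patch=(36, 36, 36), output_patch=(10, 10, 10),
                      depth=1, convs_per_block=3)

    def test_tiling_covers_every_voxel_exactly_once(self):
        shape, out = (13, 25, 30), (4, 4, 4)
        cover = np.zeros([-(-s // o) * o for s, o in zip(shape, out)], int)
        for st in tile_starts(shape, out):
            sl = tuple(slice(s, s + o) for s, o in zip(st, out))
            cover[sl] += 1
        assert np.all(cover == 1)


class TestSampler:
    def test_classes_drawn_evenly(self, tiny_case):
        cfg = tiny_cfg()
        rng = np.random.default_rng(1)
        patches = sample_training_patches(tiny_case, cfg, 1000, rng=rng)
        frac = np.mean([p.center_class == "lesion" for p in patches])
        # 99% binomial bound around 1/2 at n=1000
        assert abs(frac - 0.5) < 2.576 * np.sqrt(0.25 / 1000)

    def test_lesion_centers_really_are_lesions(self, tiny_case):
        cfg = tiny_cfg()
        patches = sample_training_patches(tiny_case, cfg, 60,
                                          rng=np.random.default_rng(2))
        truth = tiny_case.truth_seg.values
        for p in patches:
            assert truth[p.center] == (1 if p.center_class == "lesion" else 0)

    def test_unweighted_draws_are_uniform_within_class(self):
        # flat SUV below the boost reference -> all weights equal
        from petindex.volumes import VoxelGrid, PatientCase, REGION_LABELS
        sp = (3.0, 3.0, 3.0)
        shape = (6, 6, 6)
        labels = np.full(shape, REGION_LABELS["bones"], dtype=np.int32)
        truth = np.zeros(shape, dtype=np.int32)
        truth[:3] = 1
        case = PatientCase(
            "u", VoxelGrid(np.full(shape, 700.0), sp, unit_tag="HU"),
            VoxelGrid(np.full(shape, 5.0), sp, unit_tag="SUV"),
            VoxelGrid(labels, sp, unit_tag="label"),
            truth_seg=VoxelGrid(truth, sp, unit_tag="binary"))
        cfg = tiny_cfg(high_suv_boost=0.0, hard_example_boost=0.0)
        rng = np.random.default_rng(3)
        counts = np.zeros(shape)
        n_draws = 8000
        for _ in range(8):
            for p in sample_training_patches(case, cfg, n_draws // 8, rng=rng):
                counts[p.center] += 1
        for cls_mask in (truth.astype(bool), ~truth.astype(bool)):
            obs = counts[cls_mask]
            chi2 = ((obs - obs.mean()) ** 2 / obs.mean()).sum()
            crit = stats.chi2.ppf(0.99, df=obs.size - 1)
            assert chi2 < crit  # uniformity not rejected at alpha=0.01

    def test_hard_example_voxel_dominates_background_draws(self, tiny_case):
        cfg = tiny_cfg(hard_example_boost=500.0, high_suv_boost=0.0)
        mis = np.zeros(tiny_case.truth_seg.shape, dtype=np.int32)
        target = (2, 3, 4)
        assert tiny_case.truth_seg.values[target] == 0
        mis[target] = 1
        mis_grid = tiny_case.truth_seg.with_values(mis, "binary")
        rng = np.random.default_rng(4)
        counts: dict = {}
        for _ in range(10):
            for p in sample_training_patches(tiny_case, cfg, 1000,
                                             misclassified_map=mis_grid,
                                             rng=rng):
                if p.center_class == "background":
                    counts[p.center] = counts.get(p.center, 0) + 1
        top = max(counts, key=counts.get)
        assert top == target

    def test_lesion_free_case_raises_sampling_error(self):
        case = generate_phantom(PhantomSpec(shape=(24, 24, 24),
                                            spacing_mm=(3.0, 3.0, 3.0),
                                            n_lesions=0, seed=5))
        with pytest.raises(SamplingError):
            # n large enough that some lesion-class draws are requested
            sample_training_patches(case, tiny_cfg(), 50,
                                    rng=np.random.default_rng(0))

    def test_border_patches_are_padded_not_cropped(self, tiny_case):
        cfg = tiny_cfg()
        patches = sample_training_patches(tiny_case, cfg, 40,
                                          rng=np.random.default_rng(6))
        for p in patches:
            assert p.inputs.shape == (cfg.in_channels, *cfg.input_patch)
            assert p.target.shape == cfg.output_patch


class TestNetworkNumerics:
    def test_softmax_probabilities_sum_to_one(self):
        net = UNet3D(in_channels=4, depth=1, convs_per_block=1,
                     base_filters=4, seed=0)
        x = np.random.default_rng(0).normal(size=(2, 4, 12, 12, 12))
        p = net.predict_proba(x)
        assert p.shape == (2, 2, 4, 4, 4)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_gradients_match_finite_differences(self):
        # spot-check analytic backprop against numeric gradients
        net = UNet3D(in_channels=2, depth=1, convs_per_block=1,
                     base_filters=2, seed=1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 2, 12, 12, 12)).astype(np.float32)
        t = rng.integers(0, 2, size=(1, 4, 4, 4))

        def loss_of():
            return softmax_cross_entropy(net.forward(x), t)[0]

        loss, grad = softmax_cross_entropy(net.forward(x), t)
        net.backward(grad)
        eps = 1e-3
        checked = 0
        for w, g in net.params():
            flat_w, flat_g = w.ravel(), g.ravel()
            for idx in rng.choice(flat_w.size, size=min(3, flat_w.size),
                                  replace=False):
                orig = flat_w[idx]
                flat_w[idx] = orig + eps
                lp = loss_of()
                flat_w[idx] = orig - eps
                lm = loss_of()
                flat_w[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(flat_g[idx],
                                                abs=2e-3, rel=5e-2)
                checked += 1
        assert checked >= 12

    def test_training_is_deterministic_under_seed(self, tiny_case):
        cfg = tiny_cfg(epochs=2, patches_per_epoch=8)
        m1 = train_model([tiny_case], cfg)
        m2 = train_model([tiny_case], cfg)
        assert m1.epoch_losses == m2.epoch_losses
        for (w1, _), (w2, _) in zip(m1.net.params(), m2.net.params()):
            assert np.array_equal(w1, w2)

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            train_model([], tiny_cfg())


@pytest.fixture(scope="module")
def tiny_model(tiny_case):
    return train_model([tiny_case], tiny_cfg(epochs=1, patches_per_epoch=8))


class TestInference:
    def test_probability_volume_covers_case_grid(self, tiny_model, tiny_case):
        prob = predict_volume(tiny_model, tiny_case)
        assert prob.shape == tiny_case.pet.shape
        assert prob.unit_tag == "probability"
        assert prob.values.min() >= 0.0 and prob.values.max() <= 1.0

    def test_channel_mismatch_is_contract_error(self, tiny_model, tiny_case):
        bad_cfg = tiny_cfg(regions=("bones",))  # 3 channels, model has 4
        with pytest.raises(ValueError, match="channels"):
            predict_volume(tiny_model, tiny_case, bad_cfg)

    def test_label_mask_conditioning_is_live(self, tiny_model, tiny_case):
        # zeroing the label channels must change the predictions
        cfg = tiny_model.cfg
        channels = encode_channels(tiny_case, cfg)
        x = channels[None, :, :12, :12, :12].copy()
        base = tiny_model.net.predict_proba(x)
        x2 = x.copy()
        x2[:, 2:] = 0.0
        ablated = tiny_model.net.predict_proba(x2)
        assert not np.allclose(base, ablated)

    def test_checkpoint_roundtrip_preserves_predictions(self, tiny_model,
                                                        tiny_case, tmp_path):
        tiny_model.save(tmp_path / "model")
        back = LesionModel.load(tmp_path / "model.npz")
        a = predict_volume(tiny_model, tiny_case)
        b = predict_volume(back, tiny_case)
        assert np.array_equal(a.values, b.values)
        assert (tmp_path / "model.json").exists()
        assert (tmp_path / "model.losses.csv").exists()
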