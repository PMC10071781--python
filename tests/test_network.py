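"""Cascade model: zero-init identity, composition, losses, augmentation, training."""

import inspect

import numpy as np
import pytest

from petnorm import _autodiff as ad
from petnorm import phantom as ph
from petnorm.geometry import compose_displacements
from petnorm.network import (CascadeConfig, CascadeModel, TrainConfig, TrainingSample,
                             augment_sample, build_model, dice_loss, ncc_loss,
                             predict_displacement, spatially_normalize, total_loss,
                             train_model, _cascade_forward)
from petnorm.volume import DisplacementField, Volume


@pytest.fixture(scope="module")
def small_pet():
    assets = ph.make_template((32, 32, 32), seed=0)
    return assets, ph.pet_from_labels(assets.tissue_labels, "positive")


class TestModelConstruction:
    def test_untrained_model_predicts_zero_field(self, small_pet):
        _, pet = small_pet
        model = build_model(CascadeConfig(), seed=0, grid_shape=pet.shape)
        fld = predict_displacement(model, pet)
        assert fld.grid_shape == pet.shape
        assert not fld.u.any()

    def test_seed_reproducibility_of_parameters(self):
        a = build_model(CascadeConfig(), seed=3)
        b = build_model(CascadeConfig(), seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_too_small_grid_rejected(self):
        cfg = CascadeConfig(levels=3, field_resolution=2)
        with pytest.raises(ValueError, match="grid"):
            build_model(cfg, seed=0, grid_shape=(8, 8, 8))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CascadeConfig(n_stages=0)
        with pytest.raises(ValueError):
            CascadeConfig(ncc_window=4)

    def test_checkpoint_roundtrip(self, tmp_path, small_pet):
        _, pet = small_pet
        model = build_model(CascadeConfig(n_stages=1, base_channels=4), seed=1)
        # give it nonzero output weights so the test is not vacuous
        model.stages[0].flow_w.data += 0.01
        model.save(tmp_path / "m.npz")
        loaded = CascadeModel.load(tmp_path / "m.npz")
        assert loaded.config == model.config
        a = predict_displacement(model, pet)
        b = predict_displacement(loaded, pet)
        assert np.array_equal(a.u, b.u)


class TestPredict:
    def test_deterministic(self, small_pet):
        _, pet = small_pet
        model = build_model(CascadeConfig(), seed=0)
        model.stages[0].flow_w.data += 0.01
        a = predict_displacement(model, pet)
        b = predict_displacement(model, pet)
        assert np.array_equal(a.u, b.u)

    def test_single_stage_equals_raw_stage_output(self, small_pet):
        _, pet = small_pet
        model = build_model(CascadeConfig(n_stages=1), seed=2)
        model.stages[0].flow_w.data += np.float32(0.02)
        fld = predict_displacement(model, pet)
        x = ad.const(pet.data.astype(np.float32)[None])
        up = ad.upsample2_linear(model.stages[0].forward(x))
        assert np.allclose(fld.u, np.moveaxis(up.data, 0, -1), atol=1e-6)

    def test_two_stage_output_matches_composition_oracle(self, small_pet):
        """The cascade's merge of stage fields must agree with the
        independent displacement-composition operation."""
        _, pet = small_pet
        model = build_model(CascadeConfig(n_stages=2), seed=4)
        for s in model.stages:
            s.flow_w.data += np.float32(0.02)
        total = predict_displacement(model, pet)

        one_stage = build_model(CascadeConfig(n_stages=1), seed=4)
        one_stage.stages[0] = model.stages[0]
        u1 = predict_displacement(one_stage, pet)

        # stage-2 refinement on (warped pet ⊕ pet), reproduced manually
        base = np.stack(np.meshgrid(*(np.arange(n, dtype=np.float32) for n in pet.shape),
                                    indexing="ij"))
        pet_c = ad.const(pet.data.astype(np.float32)[None])
        coords = ad.const(base + np.moveaxis(u1.u, -1, 0))
        warped = ad.grid_sample(pet_c, coords)
        u2_var = ad.upsample2_linear(model.stages[1].forward(ad.concat(warped, pet_c)))
        u2 = DisplacementField(u=np.moveaxis(u2_var.data, 0, -1))
        expected = compose_displacements(u1, u2)
        assert np.abs(total.u - expected.u).max() < 1e-3

    def test_forward_path_consumes_pet_alone(self):
        params = list(inspect.signature(predict_displacement).parameters)
        assert params == ["model", "pet_affine"]
        params = list(inspect.signature(spatially_normalize).parameters)
        assert "mr" not in " ".join(params)


class TestLosses:
    def test_ncc_self_correlation_is_zero(self, rng):
        a = Volume(rng.uniform(0.1, 1.0, (12, 12, 12)))
        assert ncc_loss(a, Volume(a.data.copy()), 5) == pytest.approx(0.0, abs=1e-4)

    def test_ncc_anticorrelated_is_two(self, rng):
        a = Volume(rng.uniform(0.1, 1.0, (12, 12, 12)))
        assert ncc_loss(a, Volume(-a.data + 2.0), 5) == pytest.approx(2.0, abs=1e-4)

    def test_ncc_constant_input_rule(self, rng):
        a = Volume(np.full((12, 12, 12), 0.7))
        b = Volume(rng.uniform(0.1, 1.0, (12, 12, 12)))
        assert ncc_loss(a, b, 5) == pytest.approx(1.0, abs=1e-6)

    def test_dice_identical_disjoint_halfoverlap(self):
        p = np.zeros((6, 6, 6))
        p[1:3, 1, 1] = 1
        q = np.zeros((6, 6, 6))
        q[2:4, 1, 1] = 1
        assert dice_loss(Volume(p), Volume(p.copy())) == pytest.approx(0.0, abs=0.2)
        assert dice_loss(Volume(p), Volume((p == 0) * 1.0)) == pytest.approx(1.0, abs=0.01)
        # 2-voxel masks overlapping in 1 voxel: exact closed form with s=1
        assert dice_loss(Volume(p), Volume(q)) == pytest.approx(1 - 3 / 5)

    def test_dice_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dice_loss(Volume(np.full((4, 4, 4), 1.5)), Volume(np.zeros((4, 4, 4))))

    def test_total_loss_components_recompose(self, rng):
        cfg = CascadeConfig(ncc_window=5)
        shape = (16, 16, 16)
        field = DisplacementField(u=rng.normal(0, 0.5, shape + (3,)))
        mr = Volume(rng.uniform(0, 1, shape))
        gm = Volume(rng.uniform(0, 1, shape))
        tmr = Volume(rng.uniform(0, 1, shape))
        tgm = Volume(rng.uniform(0, 1, shape))
        total, comps = total_loss(field, mr, gm, tmr, tgm, cfg)
        recomposed = (comps["ncc"] + cfg.dice_weight * comps["dice"]
                      + cfg.field_smoothing_weight * comps["smooth"])
        assert total == pytest.approx(recomposed, abs=1e-6)
        assert 0 <= comps["ncc"] <= 2 and 0 <= comps["dice"] <= 1 and comps["smooth"] >= 0

    def test_total_loss_zero_field_self_target(self, rng):
        # textured mr (local variance well above the floor) and a binary gm
        # mask make the zero-field self-comparison exact
        cfg = CascadeConfig(ncc_window=5)
        shape = (16, 16, 16)
        mr = Volume(rng.uniform(0.1, 1.0, shape))
        gm = Volume((rng.uniform(0, 1, shape) > 0.5).astype(np.float64))
        zero = DisplacementField.zeros(shape)
        total, comps = total_loss(zero, mr, gm, Volume(mr.data.copy()),
                                  Volume(gm.data.copy()), cfg)
        assert comps["smooth"] == 0
        assert comps["ncc"] == pytest.approx(0.0, abs=1e-4)
        assert comps["dice"] == pytest.approx(0.0, abs=1e-6)

    def test_weights_zero_reduces_to_ncc(self, rng):
        cfg = CascadeConfig(ncc_window=5, dice_weight=0.0, field_smoothing_weight=0.0)
        shape = (12, 12, 12)
        field = DisplacementField(u=rng.normal(0, 0.5, shape + (3,)))
        args = [Volume(rng.uniform(0, 1, shape)) for _ in range(4)]
        total, comps = total_loss(field, *args, cfg)
        assert total == comps["ncc"]


class TestAugmentation:
    def _sample(self, assets):
        pet = ph.pet_from_labels(assets.tissue_labels, "negative")
        return TrainingSample(pet_affine=pet, mr_affine=assets.template_mr,
                              gm_affine=assets.gm_probability)

    def test_zero_ranges_identity(self, small_assets):
        cfg = TrainConfig(aug_rotation_deg=0, aug_translation_vox=0, aug_scale=0,
                          aug_intensity=0, aug_elastic_amplitude=0)
        sample = self._sample(small_assets)
        out = augment_sample(sample, cfg, np.random.default_rng(0))
        assert np.array_equal(out.pet_affine.data, sample.pet_affine.data)

    def test_fixed_rng_state_reproducible(self, small_assets):
        cfg = TrainConfig()
        sample = self._sample(small_assets)
        a = augment_sample(sample, cfg, np.random.default_rng(42))
        b = augment_sample(sample, cfg, np.random.default_rng(42))
        assert np.array_equal(a.pet_affine.data, b.pet_affine.data)
        assert np.array_equal(a.gm_affine.data, b.gm_affine.data)

    def test_gm_stays_in_unit_interval(self, small_assets):
        cfg = TrainConfig(aug_elastic_amplitude=3.0, aug_intensity=0.3)
        out = augment_sample(self._sample(small_assets), cfg, np.random.default_rng(1))
        assert out.gm_affine.data.min() >= 0 and out.gm_affine.data.max() <= 1


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        assets = ph.make_template((32, 32, 32), seed=0)
        samples = []
        for seed in (1, 2, 3):
            spec = ph.PhantomSpec(grid_shape=(32, 32, 32), seed=seed, noise_sd=0.02,
                                  deform_amplitude=2.0, ventricle_scale=1.2,
                                  affine_rot_deg=0, affine_trans_vox=0, affine_scale=0,
                                  amyloid_status="positive" if seed % 2 else "negative")
            pair = ph.make_phantom_pair(spec, assets)
            samples.append(TrainingSample(pet_affine=pair.pet, mr_affine=pair.mr,
                                          gm_affine=pair.gm_segment))
        cfg = CascadeConfig(base_channels=4, ncc_window=7)
        return assets, samples, cfg

    def test_loss_decreases_and_history_shape(self, tiny_setup):
        assets, samples, cfg = tiny_setup
        model = build_model(cfg, seed=0)
        tc = TrainConfig(epochs=5, learning_rate=3e-3, seed=0)
        hist = train_model(model, samples, assets, tc)
        df = hist.to_frame()
        assert list(df.columns) == ["epoch", "total", "ncc", "dice", "smooth"]
        assert len(df) == 5
        assert df["total"].iloc[-1] < df["total"].iloc[0]
        assert "best epoch" in hist.summary()

    def test_training_fully_seeded(self, tiny_setup):
        assets, samples, cfg = tiny_setup
        histories = []
        for _ in range(2):
            model = build_model(cfg, seed=0)
            tc = TrainConfig(epochs=2, seed=7)
            histories.append(train_model(model, samples, assets, tc).to_frame())
        assert histories[0].equals(histories[1])

    def test_empty_sample_list_rejected(self, tiny_setup):
        assets, _, cfg = tiny_setup
        with pytest.raises(ValueError, match="sample"):
            train_model(build_model(cfg, seed=0), [], assets, TrainConfig(epochs=1))
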