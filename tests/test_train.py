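import numpy as np
import pytest

from stepreg import (LossConfig, NetworkConfig, SynthConfig, TrainConfig,
                     kfold_split, make_dataset, non_correspondence_mask,
                     register_pair, train, warp)
from stepreg.network import LevelConfig


def _tiny_net_cfg(seed=0, n_levels=2):
    factors = [2 ** (n_levels - 1 - i) for i in range(n_levels)]
    kernels = [5, 3][-n_levels:]
    levels = [LevelConfig(level_index=n_levels - i, kernel_size=kernels[i],
                          channels=(4, 8), factor=factors[i])
              for i in range(n_levels)]
    return NetworkConfig(n_levels=n_levels, levels=levels,
                         attention_channels=2, seed=seed)


@pytest.fixture(scope="module")
def tiny_pairs():
    cfg = SynthConfig(shape=(16, 16, 8), n_blobs=15, field_amplitude=1.0,
                      field_smoothness=3.0, cavity_radius=2.0, noise_sd=0.005,
                      n_landmarks=4, seed=50)
    cases = make_dataset(2, cfg)
    return [(c.preop, c.followup, c.pathology_mask) for c in cases]


class TestTrainLoop:
    def test_default_config_matches_published_hyperparameters(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.batch_size == 1
        assert cfg.lambda_reg == pytest.approx(0.1)
        assert cfg.epochs == 1000

    def test_loss_identity_every_epoch(self, tiny_pairs):
        tc = TrainConfig(epochs=3, learning_rate=1e-3, seed=1)
        _, log = train(tiny_pairs, _tiny_net_cfg(), tc,
                       LossConfig(ncc_window=5, lambda_reg=0.1))
        for rec in log.records:
            assert rec["total"] == pytest.approx(
                rec["similarity"] + rec["lambda_reg"] * rec["regularization"],
                abs=1e-6)

    def test_deterministic_given_seed(self, tiny_pairs):
        tc = TrainConfig(epochs=2, learning_rate=1e-3, seed=4)
        _, log1 = train(tiny_pairs, _tiny_net_cfg(seed=4), tc,
                        LossConfig(ncc_window=5))
        _, log2 = train(tiny_pairs, _tiny_net_cfg(seed=4), tc,
                        LossConfig(ncc_window=5))
        for a, b in zip(log1.records, log2.records):
            assert a["total"] == b["total"]
            assert a["similarity"] == b["similarity"]

    def test_loss_decreases_on_small_problem(self, tiny_pairs):
        tc = TrainConfig(epochs=15, learning_rate=1e-3, seed=2)
        _, log = train(tiny_pairs[:1], _tiny_net_cfg(seed=2), tc,
                       LossConfig(ncc_window=5))
        assert log.records[-1]["total"] < log.records[0]["total"]

    def test_huge_const_disables_masking(self, tiny_pairs):
        tc = TrainConfig(epochs=2, learning_rate=1e-3, seed=3, const=1e9)
        _, log = train(tiny_pairs, _tiny_net_cfg(seed=3), tc,
                       LossConfig(ncc_window=5))
        for rec in log.records:
            assert rec["mask_fraction_fwd"] == 0.0
            assert rec["mask_fraction_bwd"] == 0.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], _tiny_net_cfg(), TrainConfig(epochs=1))

    def test_mixed_shapes_rejected(self, tiny_pairs):
        other = make_dataset(1, SynthConfig(shape=(12, 12, 8), n_landmarks=4,
                                            field_amplitude=0.5, cavity_radius=1.5,
                                            field_smoothness=3.0, seed=9))[0]
        bad = tiny_pairs + [(other.preop, other.followup, other.pathology_mask)]
        with pytest.raises(ValueError):
            train(bad, _tiny_net_cfg(), TrainConfig(epochs=1))


class TestRegisterPair:
    @pytest.fixture(scope="class")
    def trained(self, tiny_pairs):
        tc = TrainConfig(epochs=2, learning_rate=1e-3, seed=5)
        model, _ = train(tiny_pairs, _tiny_net_cfg(seed=5), tc,
                         LossConfig(ncc_window=5))
        return model

    def test_result_self_consistency(self, tiny_pairs, trained):
        pre, fol, pm = tiny_pairs[0]
        res = register_pair(pre, fol, pm, trained)
        # warped equals an independent recomputation from the returned field
        expected = warp(fol.normalized().data, res.field_fwd)
        np.testing.assert_allclose(res.warped_fwd, expected, atol=1e-12)
        # masks equal the consistency module applied to the returned fields
        from stepreg.consistency import DEFAULT_CONST, const_to_voxels

        cvox = const_to_voxels(DEFAULT_CONST, res.field_fwd.shape)
        ref = non_correspondence_mask(res.field_fwd, res.field_bwd, cvox)
        np.testing.assert_array_equal(res.mask_fwd.data, ref.mask.data)

    def test_shape_mismatch_rejected(self, tiny_pairs, trained):
        from stepreg import BinaryMask, Volume

        bad = Volume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            register_pair(bad, bad, BinaryMask(np.zeros((8, 8, 8), dtype=np.uint8)),
                          trained)

    def test_save_load_round_trip(self, tiny_pairs, trained, tmp_path):
        from stepreg import Model

        p = tmp_path / "model.npz"
        trained.save(p)
        back = Model.load(p)
        pre, fol, pm = tiny_pairs[0]
        r1 = register_pair(pre, fol, pm, trained)
        r2 = register_pair(pre, fol, pm, back)
        np.testing.assert_array_equal(r1.field_fwd.u, r2.field_fwd.u)


class TestIdentityRegistration:
    def test_identical_images_fresh_model_zero_fields(self):
        """Fresh (zero-head) nets on identical images: zero fields, empty masks."""
        from stepreg.train import Model

        cfg = SynthConfig(shape=(16, 16, 8), field_amplitude=0.0,
                          cavity_radius=0.0, noise_sd=0.0, n_landmarks=4, seed=8)
        case = make_dataset(1, cfg)[0]
        model = Model(_tiny_net_cfg(seed=6), (16, 16, 8))
        res = register_pair(case.preop, case.followup, case.pathology_mask, model)
        np.testing.assert_array_equal(res.field_fwd.u, 0.0)
        np.testing.assert_array_equal(res.field_bwd.u, 0.0)
        assert res.mask_fwd.data.sum() == 0
        assert res.mask_bwd.data.sum() == 0


class TestKFold:
    def test_partition_properties(self):
        folds = kfold_split(10, 5, seed=1)
        assert len(folds) == 5
        all_val = sorted(i for _, val in folds for i in val)
        assert all_val == list(range(10))
        for trn, val in folds:
            assert not set(trn) & set(val)
            assert sorted(trn + val) == list(range(10))

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(4, 1)
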