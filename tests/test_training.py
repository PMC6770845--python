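"""Two-stage freeze/transfer training: split bookkeeping, learnability on
tiny fixtures, the bit-level freeze contract, and checkpoint round-trips."""

import dataclasses
import logging

import numpy as np
import pytest

from ccens import models, simdata, training
from ccens.training import (DEFAULT_FEATURE_CONFIG, DEFAULT_REGRESSION_CONFIG,
                            BranchWeightsMissingError, TrainingConfig,
                            freeze, load_model, make_split, save_model,
                            train_feature_stage, train_full,
                            train_regression_stage)


class TestConfig:
    def test_documented_defaults(self):
        assert DEFAULT_FEATURE_CONFIG.epochs == 192
        assert DEFAULT_FEATURE_CONFIG.batch_size == 16
        assert DEFAULT_REGRESSION_CONFIG.epochs == 1000

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainingConfig(epochs=1, batch_size=0)
        with pytest.raises(ValueError):
            TrainingConfig(epochs=1, optimizer="sgd")


class TestMakeSplit:
    def _corpus(self, n, seed):
        cfg = simdata.SceneConfig(
            height=16, width=16,
            count_law=simdata.DistSpec("uniform_int", low=1, high=4),
            cell_radius_law=simdata.DistSpec("constant", value=1.5),
            blur_sigma=0.0)
        return simdata.generate_dataset(cfg, n, seed=seed)

    def test_sizes_and_disjointness(self):
        split = make_split(self._corpus(20, 1), self._corpus(30, 2),
                           n_test_each=5, seed=0)
        assert len(split.S1) == 15 and len(split.S2) == 25
        assert len(split.T) == 10
        assert len(split.combined_counts()) == 40

    def test_same_seed_identical_membership(self):
        a = make_split(self._corpus(20, 1), self._corpus(30, 2), 5, seed=9)
        b = make_split(self._corpus(20, 1), self._corpus(30, 2), 5, seed=9)
        np.testing.assert_array_equal(a.T.counts(), b.T.counts())
        np.testing.assert_array_equal(a.S1.counts(), b.S1.counts())

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="too small"):
            make_split(self._corpus(4, 1), self._corpus(30, 2), 5)


@pytest.fixture(scope="module")
def trained_branch(tiny_arch, tiny_corpus):
    """Density branch after a short feature stage on the tiny corpus."""
    handle = models.build_density_branch(tiny_arch)
    result = train_feature_stage(handle, tiny_corpus.images(),
                                 tiny_corpus.density_maps(),
                                 TrainingConfig(epochs=5, batch_size=8,
                                                learning_rate=2e-3, seed=1))
    return handle, result


class TestFeatureStage:
    def test_loss_recorded_and_decreases(self, trained_branch):
        _, result = trained_branch
        assert result.stage == "feature"
        assert len(result.loss_history) == 5
        assert all(np.isfinite(result.loss_history))
        assert result.loss_history[-1] < result.loss_history[0]

    def test_config_recorded(self, trained_branch):
        _, result = trained_branch
        assert result.config.epochs == 5 and result.config.batch_size == 8

    def test_misaligned_targets_rejected(self, tiny_arch, tiny_corpus):
        handle = models.build_density_branch(tiny_arch)
        with pytest.raises(ValueError, match="shape-matched"):
            train_feature_stage(handle, tiny_corpus.images(),
                                tiny_corpus.density_maps()[:3],
                                TrainingConfig(epochs=1))

    def test_seeded_reproducibility(self, tiny_arch, tiny_corpus):
        histories = []
        for _ in range(2):
            h = models.build_density_branch(tiny_arch)
            r = train_feature_stage(h, tiny_corpus.images()[:8],
                                    tiny_corpus.density_maps()[:8],
                                    TrainingConfig(epochs=2, batch_size=4,
                                                   seed=11))
            histories.append(r.loss_history)
        assert histories[0] == histories[1]


class TestFreezeContract:
    def test_unknown_component(self, tiny_arch):
        m = models.build_model("DRDCNN", tiny_arch)
        with pytest.raises(ValueError, match="unknown component"):
            freeze(m, ["encoder"])

    def test_frozen_branch_bit_stable_tail_changes(self, tiny_arch,
                                                   tiny_corpus,
                                                   trained_branch):
        branch_handle, _ = trained_branch
        m = models.build_model("DRDCNN", tiny_arch)
        m.components["density_branch"] = branch_handle.components["density_branch"]
        freeze(m, ["density_branch"])
        before_branch = {k: v.copy() for k, v in m.get_weights().items()
                         if k.startswith("density_branch/")}
        before_tail = {k: v.copy() for k, v in m.get_weights().items()
                       if k.startswith("tail/")}
        train_regression_stage(m, tiny_corpus.images(), tiny_corpus.counts(),
                               TrainingConfig(epochs=2, batch_size=8, seed=2))
        after = m.get_weights()
        for k, v in before_branch.items():
            np.testing.assert_array_equal(after[k], v, err_msg=k)
        assert any(not np.array_equal(after[k], v)
                   for k, v in before_tail.items())

    def test_unfrozen_branch_warns_and_trains(self, tiny_arch, tiny_corpus,
                                              caplog):
        m = models.build_model("DRDCNN", tiny_arch)
        before = {k: v.copy() for k, v in m.get_weights().items()
                  if k.startswith("density_branch/") and k.endswith("/w")}
        with caplog.at_level(logging.WARNING, logger="ccens"):
            train_regression_stage(m, tiny_corpus.images()[:8],
                                   tiny_corpus.counts()[:8],
                                   TrainingConfig(epochs=1, batch_size=4,
                                                  seed=3))
        assert any("unfrozen" in r.message for r in caplog.records)
        after = m.get_weights()
        assert any(not np.array_equal(after[k], v) for k, v in before.items())


class TestRegressionStage:
    def test_loss_decreases_on_fixture(self, tiny_arch, tiny_corpus,
                                       trained_branch):
        branch_handle, _ = trained_branch
        m = models.build_model("DRDCNN", tiny_arch)
        m.components["density_branch"] = branch_handle.components["density_branch"]
        freeze(m, ["density_branch"])
        res = train_regression_stage(m, tiny_corpus.images(),
                                     tiny_corpus.counts(),
                                     TrainingConfig(epochs=20, batch_size=8,
                                                    learning_rate=2e-3,
                                                    seed=4))
        assert res.stage == "regression"
        assert len(res.loss_history) == 20
        assert (np.median(res.loss_history[-3:])
                < np.median(res.loss_history[:3]))

    def test_degenerate_constant_targets(self, tiny_arch, tiny_corpus,
                                         trained_branch):
        branch_handle, _ = trained_branch
        m = models.build_model("DRDCNN", tiny_arch, seed=5)
        m.components["density_branch"] = branch_handle.components["density_branch"]
        freeze(m, ["density_branch"])
        counts = np.full(len(tiny_corpus), 6.0)
        train_regression_stage(m, tiny_corpus.images(), counts,
                               TrainingConfig(epochs=100, batch_size=8,
                                              learning_rate=2e-3, seed=5))
        pred = models.predict_counts(m, tiny_corpus.images())
        # predictions cluster tightly near the constant; a residual
        # eval-time attenuation remains because dropout(0.6) feeds the
        # final max-pool -> dense stage, which no batch-norm recalibrates
        assert pred.std() < 1.0
        assert np.abs(pred - 6.0).mean() <= 0.35 * 6.0

    def test_negative_counts_rejected(self, tiny_arch, tiny_corpus):
        m = models.build_model("DRDCNN", tiny_arch)
        with pytest.raises(ValueError, match="non-negative"):
            train_regression_stage(m, tiny_corpus.images(),
                                   -tiny_corpus.counts(),
                                   TrainingConfig(epochs=1))

    def test_ddcnn_has_no_tail_to_train(self, tiny_arch, tiny_corpus):
        m = models.build_model("DDCNN", tiny_arch)
        with pytest.raises(ValueError, match="no regression tail"):
            train_regression_stage(m, tiny_corpus.images(),
                                   tiny_corpus.counts(),
                                   TrainingConfig(epochs=1))


class TestTrainFull:
    def test_erdcnn_requires_branch_weights(self, tiny_arch, tiny_split):
        with pytest.raises(BranchWeightsMissingError, match="branch weights"):
            train_full("ERDCNN", tiny_split,
                       TrainingConfig(epochs=1), TrainingConfig(epochs=1),
                       arch=tiny_arch)

    def test_drdcnn_staging_and_freeze(self, tiny_arch, tiny_split):
        m = train_full("DRDCNN", tiny_split,
                       TrainingConfig(epochs=2, batch_size=8, seed=6),
                       TrainingConfig(epochs=2, batch_size=8, seed=7),
                       arch=tiny_arch)
        assert [r.stage for r in m.stage_results] == ["feature", "regression"]
        assert m.trainable["density_branch"] is False

    def test_ddcnn_has_no_tail(self, tiny_arch, tiny_split):
        m = train_full("DDCNN", tiny_split,
                       TrainingConfig(epochs=1, batch_size=8, seed=6), None,
                       arch=tiny_arch)
        assert "tail" not in m.components
        assert [r.stage for r in m.stage_results] == ["feature"]

    def test_erdcnn_transfers_branches_exactly(self, tiny_arch, tiny_split,
                                               trained_branch):
        branch_handle, _ = trained_branch
        mask_handle = models.build_mask_branch(tiny_arch)
        m = train_full("ERDCNN", tiny_split, None,
                       TrainingConfig(epochs=1, batch_size=8, seed=8),
                       arch=tiny_arch,
                       branches={"density_branch": branch_handle,
                                 "mask_branch": mask_handle})
        src = branch_handle.get_weights()
        dst = m.get_weights()
        for k, v in src.items():
            np.testing.assert_array_equal(dst[k], v)


class TestSerialization:
    def test_roundtrip_bit_identical_predictions(self, tmp_path, tiny_arch,
                                                 tiny_corpus):
        m = models.build_model("ERDCNN", tiny_arch, seed=9)
        save_model(m, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        assert back.kind == "ERDCNN"
        imgs = tiny_corpus.images()[:4]
        np.testing.assert_array_equal(models.predict_counts(m, imgs),
                                      models.predict_counts(back, imgs))

    def test_wrong_shape_weights_rejected(self, tmp_path, tiny_arch):
        m = models.build_model("DRDCNN", tiny_arch)
        save_model(m, tmp_path / "ckpt")
        import json
        desc = json.loads((tmp_path / "ckpt" / "model.json").read_text())
        desc["config"]["unet_base_filters"] = 8  # weights no longer fit
        (tmp_path / "ckpt" / "model.json").write_text(json.dumps(desc))
        with pytest.raises(ValueError, match="shape mismatch"):
            load_model(tmp_path / "ckpt")

    def test_branch_checkpoint_roundtrip(self, tmp_path, tiny_arch,
                                         trained_branch):
        branch_handle, _ = trained_branch
        save_model(branch_handle, tmp_path / "branch")
        back = load_model(tmp_path / "branch")
        assert back.kind == "density_branch"
        for k, v in branch_handle.get_weights().items():
            np.testing.assert_array_equal(back.get_weights()[k], v)
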