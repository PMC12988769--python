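"""Schedule, EMA, early stopping, checkpointing, fit and fine-tune behavior."""

import math

import numpy as np
import pandas as pd
import pytest

from klgrade.experiments import (
    materialize,
    internal_spec,
    tiny_model_config,
    tiny_train_config,
)
from klgrade.manifest import patient_wise_split
from klgrade.model import build_model
from klgrade.train import (
    TrainConfig,
    ema_update,
    finetune,
    fit,
    load_checkpoint,
    lr_at,
    save_checkpoint,
)


class TestSchedule:
    def test_end_of_warmup_hits_base_rates(self):
        cfg = TrainConfig()
        b, h = lr_at(cfg.warmup_epochs, cfg)
        assert abs(b - cfg.base_lr) < 1e-15
        assert abs(h - 2 * cfg.base_lr) < 1e-15

    def test_cosine_tail_nearly_zero(self):
        cfg = TrainConfig()
        b, _ = lr_at(cfg.max_epochs - 1, cfg)
        assert b < 0.01 * cfg.base_lr

    def test_decay_midpoint_is_half_base(self):
        cfg = TrainConfig(warmup_epochs=0, max_epochs=60)
        b, _ = lr_at(30, cfg)
        assert abs(b - cfg.base_lr / 2) < 1e-12

    def test_linear_warmup_ramp(self):
        cfg = TrainConfig(warmup_epochs=3)
        rates = [lr_at(e, cfg)[0] for e in range(3)]
        np.testing.assert_allclose(
            rates, cfg.base_lr * np.array([1, 2, 3]) / 3, rtol=1e-12
        )

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at(60, TrainConfig(max_epochs=60))

    def test_finetune_overrides_rates(self):
        cfg = TrainConfig(finetune=True)
        b, h = lr_at(cfg.resolved().warmup_epochs, cfg)
        assert abs(b - 1e-5) < 1e-18
        assert abs(h - 5e-5) < 1e-18
        assert cfg.resolved().patience == 5
        assert cfg.resolved().max_epochs == 15


class TestEma:
    def test_decay_zero_copies_raw(self):
        ema = {"w": np.array([1.0, 2.0])}
        raw = {"w": np.array([5.0, 6.0])}
        ema_update(ema, raw, 0.0)
        np.testing.assert_array_equal(ema["w"], raw["w"])

    def test_decay_one_freezes(self):
        ema = {"w": np.array([1.0])}
        ema_update(ema, {"w": np.array([9.0])}, 1.0)
        assert ema["w"][0] == 1.0

    def test_geometric_closed_form(self):
        """n steps toward a constant: ema = w + decay^n (ema0 - w)."""
        decay, n, w0, target = 0.9, 25, 3.0, -1.0
        ema = {"w": np.array([w0])}
        raw = {"w": np.array([target])}
        for _ in range(n):
            ema_update(ema, raw, decay)
        expected = target + decay**n * (w0 - target)
        assert abs(ema["w"][0] - expected) < 1e-12

    def test_structure_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ema_update({"a": np.zeros(2)}, {"b": np.zeros(2)}, 0.5)


@pytest.fixture(scope="module")
def tiny_data():
    manifest, store = materialize(internal_spec(seed=21))
    assignment = patient_wise_split(manifest, seed=21)
    return manifest, store, assignment


class TestFit:
    def test_easy_signal_reaches_high_val_qwk(self, study):
        """600-image cohort, 64x64, clear ordinal cue: val QWK > 0.8 in 10 epochs."""
        state = study.train_state
        assert len(state.epoch_log) <= 10
        assert state.best_val_qwk > 0.8

    def test_best_val_qwk_monotone_in_log(self, study):
        best = study.train_state.epoch_log["best_val_qwk"].to_numpy()
        assert (np.diff(best) >= 0).all()

    def test_loss_decreases_on_separable_problem(self, study):
        log = study.train_state.epoch_log
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]

    def test_early_stopping_with_patience_one(self, tiny_data):
        """A model trained at lr=0 cannot improve: stops after patience runs out."""
        manifest, store, assignment = tiny_data
        model = build_model(tiny_model_config(seed=3))
        cfg = TrainConfig(base_lr=1e-300, warmup_epochs=0, max_epochs=30,
                          patience=1, seed=3, augment=False)
        state = fit(model, assignment.subset(manifest, "train"),
                    assignment.subset(manifest, "val"), store, cfg)
        assert len(state.epoch_log) == 2  # epoch 0 improves from -inf, epoch 1 stops

    def test_same_seed_identical_logs(self, tiny_data):
        manifest, store, assignment = tiny_data
        logs = []
        for _ in range(2):
            model = build_model(tiny_model_config(seed=5))
            cfg = TrainConfig(base_lr=1e-3, warmup_epochs=1, max_epochs=2,
                              patience=2, seed=5)
            state = fit(model, assignment.subset(manifest, "train"),
                        assignment.subset(manifest, "val"), store, cfg)
            logs.append(state.epoch_log)
        pd.testing.assert_frame_equal(logs[0], logs[1])

    def test_empty_split_rejected(self, tiny_data):
        manifest, store, assignment = tiny_data
        from klgrade.manifest import CohortManifest

        empty = CohortManifest(manifest.frame.iloc[0:0])
        with pytest.raises(ValueError, match="empty"):
            fit(build_model(tiny_model_config(seed=1)), empty,
                assignment.subset(manifest, "val"), store, TrainConfig())


class TestCheckpoint:
    def test_round_trip_preserves_outputs_and_metadata(self, tmp_path, study):
        from klgrade.inference import predict_cohort
        from klgrade.decode import Cutpoints

        model = study.model
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, study.finetune_state,
                        study.external_cutpoints, cutpoint_partition="valhash")
        loaded, meta = load_checkpoint(path)
        a = model.state_dict()
        b = loaded.state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        assert meta["cutpoints"].values == study.external_cutpoints.values
        assert meta["cutpoint_partition"] == "valhash"
        # re-evaluation reproduces the stored validation QWK exactly
        man = study.manifests["external"]
        split = study.splits["external"]
        store = study.stores["external"]
        from klgrade.train import _eval_split
        from klgrade.preprocess import eval_bundle
        val = split.subset(man, "val")
        bundles = [eval_bundle(store.get(n), model.config.image_size,
                               model.config.patch_size)
                   for n in val.frame["image"]]
        _, _, qwk_val = _eval_split(loaded, bundles,
                                    val.frame["kl_grade"].to_numpy(),
                                    study.finetune_state.config.loss_weights,
                                    1.0, 32)
        assert abs(qwk_val - study.finetune_state.best_val_qwk) < 1e-12


class TestFinetune:
    def test_zero_epochs_returns_weights_unchanged(self, tiny_data):
        manifest, store, assignment = tiny_data
        model = build_model(tiny_model_config(seed=2))
        before = model.state_dict()
        cfg = TrainConfig(finetune=True, finetune_max_epochs=0)
        state = finetune(model, assignment.subset(manifest, "train"),
                         assignment.subset(manifest, "val"), store, cfg)
        for k, v in before.items():
            np.testing.assert_array_equal(v, state.best_weights[k])

    def test_improves_domain_shifted_validation(self, study):
        """Fine-tuning on the shifted cohort beats zero-shot on its held-out test."""
        assert study.finetuned_qwk > study.zero_shot_qwk
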