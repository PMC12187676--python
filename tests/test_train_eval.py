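"""Training loop: the patience rule on scripted sequences, checkpointing,
determinism, the single-batch overfit harness, ablation bookkeeping."""

import numpy as np
import pytest

from hasaseg.config import ModelConfig, TrainConfig
from hasaseg.losses import hybrid_loss
from hasaseg.network import build_model
from hasaseg.nn import Tensor
from hasaseg.synthetic import PhantomSpec, generate_samples
from hasaseg.train_eval import (EarlyStopper, overfit_single_batch,
                                run_ablation, simulate_early_stopping, train)

TINY32 = dict(base_channels=8, depth=4, blocks_per_stage=1)


def _tiny_dataset(n=8, size=32, seed=0):
    return generate_samples(PhantomSpec(size=(size, size)), n, seed=seed,
                            slices_per_case=2)


class TestEarlyStopping:
    def test_five_consecutive_flat_epochs_stop_training(self):
        seq = [0.5, 0.6, 0.61, 0.61, 0.61, 0.61, 0.61, 0.61, 0.7]
        stop_epoch, best_epoch = simulate_early_stopping(seq, patience=5)
        assert stop_epoch == 8          # the 0.7 epoch is never reached
        assert best_epoch == 3

    def test_improvement_resets_patience(self):
        seq = [0.5, 0.5, 0.5, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6]
        stop_epoch, best_epoch = simulate_early_stopping(seq, patience=5)
        assert stop_epoch == 9 and best_epoch == 4

    def test_monotone_sequence_never_stops(self):
        seq = [0.1 * i for i in range(1, 11)]
        stop_epoch, best_epoch = simulate_early_stopping(seq, patience=5)
        assert stop_epoch == 10 and best_epoch == 10

    def test_sub_min_delta_gain_counts_as_no_improvement(self):
        stopper = EarlyStopper(patience=2, min_delta=1e-5)
        assert stopper.update(0.5, 1)
        assert not stopper.update(0.5 + 1e-7, 2)
        assert not stopper.update(0.5 + 2e-7, 3)
        assert stopper.should_stop

    def test_invalid_patience_rejected(self):
        with pytest.raises(ValueError):
            EarlyStopper(patience=0)


class TestTrain:
    def _cfg(self, **kw):
        base = dict(batch_size=4, max_epochs=1, augment=None, seed=0)
        base.update(kw)
        return TrainConfig(**base)

    def test_single_epoch_stops_with_max_epochs_reason(self):
        samples = _tiny_dataset(10)
        model = build_model(ModelConfig(**TINY32), seed=0)
        model, log = train(model, samples[:8], samples[8:], self._cfg())
        assert len(log.epochs) == 1
        assert log.stop_reason == "max_epochs"
        assert log.best_epoch == 1

    def test_fixed_seed_reproduces_epoch_one_loss(self):
        samples = _tiny_dataset(10)
        losses = []
        for _ in range(2):
            model = build_model(ModelConfig(**TINY32), seed=0)
            _, log = train(model, samples[:8], samples[8:],
                           self._cfg(augment=None))
            losses.append(log.epochs[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_returned_model_carries_best_validation_weights(self):
        samples = _tiny_dataset(12)
        model = build_model(ModelConfig(**TINY32), seed=0)
        cfg = self._cfg(max_epochs=3, lr=1e-3)
        model, log = train(model, samples[:8], samples[8:], cfg)
        best = max(e["val_dsc"] for e in log.epochs)
        assert log.epochs[log.best_epoch - 1]["val_dsc"] == best
        from hasaseg.train_eval import validate
        dsc, _ = validate(model, samples[8:], cfg)
        assert dsc == pytest.approx(best, abs=1e-12)

    def test_divergence_aborts_with_diagnostic(self):
        samples = _tiny_dataset(6)
        model = build_model(ModelConfig(**TINY32), seed=0)
        model.head.weight.data[...] = np.nan
        with pytest.raises(FloatingPointError, match="diverged"):
            train(model, samples[:4], samples[4:], self._cfg())

    def test_log_serializes_with_curves(self, tmp_path):
        samples = _tiny_dataset(8)
        model = build_model(ModelConfig(**TINY32), seed=0)
        _, log = train(model, samples[:6], samples[6:], self._cfg())
        log.write(tmp_path / "log.csv", tmp_path / "curves.png")
        assert (tmp_path / "log.csv").exists()
        assert (tmp_path / "curves.png").stat().st_size > 0


class TestOverfitHarness:
    def test_zero_steps_returns_initial_loss(self):
        batch = _tiny_dataset(4)
        model = build_model(ModelConfig(**TINY32), seed=0)
        final, history = overfit_single_batch(model, batch, steps=0)
        assert history == []
        images = np.stack([s.image for s in batch])
        masks = np.stack([s.mask for s in batch]).astype(np.int64)
        model.train()
        direct = hybrid_loss(model(Tensor(images)), masks).value
        assert final == pytest.approx(direct, rel=1e-6)

    def test_loss_trajectory_is_finite_and_decreasing(self):
        batch = _tiny_dataset(4)
        model = build_model(ModelConfig(**TINY32), seed=0)
        final, history = overfit_single_batch(model, batch, steps=40, lr=1e-3)
        assert np.all(np.isfinite(history))
        assert final < history[0]

    def test_learnable_at_adequate_budget(self):
        """The package's sanity operating point: lr 1e-3, 900 steps drives the
        hybrid loss under 0.15 on four 64x64 phantoms (tiny preset)."""
        batch = generate_samples(PhantomSpec(size=(64, 64)), 4, seed=0)
        model = build_model(ModelConfig.tiny(), seed=0)
        final, _ = overfit_single_batch(model, batch, steps=900, lr=1e-3)
        assert final < 0.15


class TestAblationBookkeeping:
    def test_two_presets_two_seeds_yield_four_rows(self):
        samples = _tiny_dataset(12)
        presets = {"a": dict(use_hfef=False, use_asa=False),
                   "b": dict(use_hfef=True, use_asa=False)}
        cfg = TrainConfig(batch_size=4, max_epochs=1, augment=None)
        table = run_ablation(samples[:8], samples[8:10], samples[10:], presets,
                             [0, 1], cfg, model_cfg=ModelConfig(**TINY32))
        assert len(table) == 4
        assert set(table["preset"]) == {"a", "b"}
        for m in ("dsc", "iou", "precision", "recall"):
            assert np.all(np.isfinite(table[m]))

    def test_identical_preset_and_seed_give_identical_rows(self):
        samples = _tiny_dataset(10)
        presets = {"a": dict(use_hfef=False, use_asa=False),
                   "a2": dict(use_hfef=False, use_asa=False)}
        cfg = TrainConfig(batch_size=4, max_epochs=1, augment=None)
        table = run_ablation(samples[:6], samples[6:8], samples[8:], presets,
                             [0], cfg, model_cfg=ModelConfig(**TINY32))
        a = table[table.preset == "a"].drop(columns=["preset"]).iloc[0]
        b = table[table.preset == "a2"].drop(columns=["preset"]).iloc[0]
        assert a.equals(b)

    def test_single_preset_rejected(self):
        with pytest.raises(ValueError, match="presets"):
            run_ablation([], [], [], {"a": {}}, [0], TrainConfig())
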