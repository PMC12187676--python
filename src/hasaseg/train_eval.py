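"""Training loop with early stopping on validation DSC, plus harnesses.

Each epoch shuffles the training set, applies online augmentation, runs
forward/backward through the hybrid CE+Dice loss and takes Adam steps.
After every epoch the validation macro DSC (foreground classes by default)
is computed; training stops when it fails to improve by at least
``min_delta`` for ``early_stop_patience`` consecutive epochs, or at
``max_epochs``.  The best-DSC parameters are restored at the end.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .config import ModelConfig, TrainConfig
from .data_io import NUM_CLASSES, Sample, augment
from .losses import hybrid_loss
from .metrics import evaluate_dataset
from .network import HasaResUNet, build_model
from .nn import Adam, Tensor

__all__ = ["EarlyStopper", "TrainLog", "train", "validate",
           "overfit_single_batch", "run_ablation", "ABLATION_PRESETS"]


class EarlyStopper:
    """Stop when the monitored value fails to improve for ``patience`` epochs.

    'Improve' means exceeding the running best by at least ``min_delta``.
    """

    def __init__(self, patience: int = 5, min_delta: float = 1e-5):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.best_epoch: int | None = None
        self.bad_epochs = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record one epoch's value (1-based ``epoch``); True if improved."""
        if value > self.best + self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self.bad_epochs = 0
            return True
        self.bad_epochs += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.bad_epochs >= self.patience


def simulate_early_stopping(values, patience: int = 5, min_delta: float = 1e-5
                            ) -> tuple[int, int]:
    """Run the stopping rule on a scripted monitor sequence.

    Returns (epochs run, best epoch), both 1-based; the sequence ends early
    when patience is exhausted.
    """
    stopper = EarlyStopper(patience, min_delta)
    epoch = 0
    for epoch, v in enumerate(values, start=1):
        stopper.update(v, epoch)
        if stopper.should_stop:
            break
    return epoch, stopper.best_epoch


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int | None = None
    stop_reason: str = ""

    @property
    def best_val_dsc(self) -> float:
        return max(e["val_dsc"] for e in self.epochs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def write(self, csv_path: str | Path, curves_png: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(csv_path, index=False)
        if curves_png is not None:
            self.plot(curves_png)

    def plot(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        df = self.to_frame()
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].plot(df["epoch"], df["train_loss"], label="train")
        axes[0].plot(df["epoch"], df["val_loss"], label="validation")
        axes[0].set_xlabel("epoch"); axes[0].set_ylabel("hybrid loss")
        axes[0].legend()
        axes[1].plot(df["epoch"], df["val_dsc"])
        axes[1].set_xlabel("epoch"); axes[1].set_ylabel("validation DSC")
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)


def _batches(samples: list[Sample], batch_size: int, rng: np.random.Generator | None):
    order = np.arange(len(samples))
    if rng is not None:
        rng.shuffle(order)
    for i in range(0, len(order), batch_size):
        chunk = [samples[j] for j in order[i:i + batch_size]]
        yield (np.stack([s.image for s in chunk]),
               np.stack([s.mask for s in chunk]).astype(np.int64))


def _loss_on_batch(model, images, masks, cfg: TrainConfig):
    probs = model(Tensor(images))
    return hybrid_loss(probs, masks, w1=cfg.loss.w1, w2=cfg.loss.w2,
                       dice_epsilon=cfg.loss.dice_epsilon,
                       include_background=cfg.loss.include_background)


def validate(model: HasaResUNet, samples: list[Sample], cfg: TrainConfig,
             num_classes: int = NUM_CLASSES) -> tuple[float, float]:
    """(macro DSC, mean hybrid loss) on a sample list, in inference mode."""
    model.eval()
    losses = []
    with nn.no_grad():
        for images, masks in _batches(samples, cfg.batch_size, rng=None):
            losses.append(_loss_on_batch(model, images, masks, cfg).value)
    report = evaluate_dataset(model, samples, num_classes=num_classes,
                              batch_size=cfg.batch_size)
    dsc = report.macro("dsc", include_background=cfg.monitor_background)
    return float(dsc), float(np.mean(losses))


def train(model: HasaResUNet, train_set: list[Sample], val_set: list[Sample],
          cfg: TrainConfig, num_classes: int = NUM_CLASSES,
          verbose: bool = False) -> tuple[HasaResUNet, TrainLog]:
    """Fit ``model``; returns it with best-validation-DSC weights restored."""
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas)
    stopper = EarlyStopper(cfg.early_stop_patience, cfg.min_delta)
    log = TrainLog()
    best_state = None
    stop_reason = "max_epochs"

    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        epoch_losses = []
        for images, masks in _batches(train_set, cfg.batch_size, rng):
            if cfg.augment is not None:
                aug = [augment(Sample(im, mk.astype(np.uint8), "b"), cfg.augment, rng)
                       for im, mk in zip(images, masks)]
                images = np.stack([s.image for s in aug])
                masks = np.stack([s.mask for s in aug]).astype(np.int64)
            optimizer.zero_grad()
            loss = _loss_on_batch(model, images, masks, cfg)
            if not np.isfinite(loss.value):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(ce={loss.ce:.4g}, dice={loss.dice:.4g})")
            loss.total.backward()
            optimizer.step()
            epoch_losses.append(loss.value)

        val_dsc, val_loss = validate(model, val_set, cfg, num_classes)
        improved = stopper.update(val_dsc, epoch)
        if improved:
            best_state = copy.deepcopy(model.state_dict())
        log.epochs.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                           "val_loss": val_loss, "val_dsc": val_dsc})
        if verbose:
            print(f"epoch {epoch}: train {np.mean(epoch_losses):.4f} "
                  f"val {val_loss:.4f} dsc {val_dsc:.4f}")
        if stopper.should_stop:
            stop_reason = "patience_exhausted"
            break

    log.best_epoch = stopper.best_epoch
    log.stop_reason = stop_reason
    if best_state is not None:
        model.load_state_dict(best_state)
    if cfg.checkpoint_dir:
        from .network import save_checkpoint
        save_checkpoint(Path(cfg.checkpoint_dir) / "best.npz", model)
    return model, log


def overfit_single_batch(model: HasaResUNet, batch: list[Sample], steps: int,
                         lr: float = 1e-4, loss_cfg=None) -> tuple[float, list[float]]:
    """Adam iterations on one fixed batch, no augmentation; a learnability
    harness — a healthy network/loss pair drives the hybrid loss near zero.

    Returns (final loss, per-step loss history); ``steps=0`` evaluates only.
    """
    from .config import LossConfig
    loss_cfg = loss_cfg or LossConfig()
    images = np.stack([s.image for s in batch])
    masks = np.stack([s.mask for s in batch]).astype(np.int64)
    optimizer = Adam(model.parameters(), lr=lr)
    model.train()
    history = []
    for _ in range(steps):
        optimizer.zero_grad()
        probs = model(Tensor(images))
        loss = hybrid_loss(probs, masks, w1=loss_cfg.w1, w2=loss_cfg.w2,
                           dice_epsilon=loss_cfg.dice_epsilon,
                           include_background=loss_cfg.include_background)
        if not np.isfinite(loss.value):
            raise FloatingPointError("overfit harness diverged")
        loss.total.backward()
        optimizer.step()
        history.append(loss.value)
    with nn.no_grad():
        probs = model(Tensor(images))
        final = hybrid_loss(probs, masks, w1=loss_cfg.w1, w2=loss_cfg.w2,
                            dice_epsilon=loss_cfg.dice_epsilon,
                            include_background=loss_cfg.include_background).value
    return final, history


ABLATION_PRESETS = {
    "resunet": dict(use_hfef=False, use_asa=False),
    "resunet+hfef": dict(use_hfef=True, use_asa=False),
    "resunet+asa": dict(use_hfef=False, use_asa=True),
    "resunet+hfef+asa": dict(use_hfef=True, use_asa=True),
}


def run_ablation(train_set: list[Sample], val_set: list[Sample],
                 test_set: list[Sample], presets: dict[str, dict],
                 seeds: list[int], train_cfg: TrainConfig,
                 model_cfg: ModelConfig | None = None,
                 num_classes: int = NUM_CLASSES, verbose: bool = False
                 ) -> pd.DataFrame:
    """Train each preset on the same split per seed; tabulate test metrics.

    Returns a long-form frame with one row per (preset, seed) carrying the
    macro metrics plus per-class DSC/IoU columns, from which mean +/- sd
    summaries per preset can be aggregated.
    """
    if len(presets) < 2:
        raise ValueError("need at least 2 presets")
    if not seeds:
        raise ValueError("need at least 1 seed")
    base_cfg = model_cfg or ModelConfig.tiny()
    rows = []
    for seed in seeds:
        for name, flags in presets.items():
            import dataclasses
            cfg = dataclasses.replace(base_cfg, **flags)
            model = build_model(cfg, seed=seed)
            tcfg = dataclasses.replace(train_cfg, seed=seed)
            model, log = train(model, train_set, val_set, tcfg,
                               num_classes=num_classes, verbose=verbose)
            report = evaluate_dataset(model, test_set, num_classes=num_classes,
                                      batch_size=tcfg.batch_size)
            row = {"preset": name, "seed": seed,
                   "epochs": len(log.epochs), "best_epoch": log.best_epoch}
            for m in ("dsc", "iou", "precision", "recall"):
                row[m] = report.macro(m, include_background=True)
                row[f"{m}_foreground"] = report.macro(m, include_background=False)
            for c, (d, i_) in enumerate(zip(report.per_class["dsc"],
                                            report.per_class["iou"])):
                row[f"dsc_c{c}"] = d
                row[f"iou_c{c}"] = i_
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of the macro metrics per preset over seeds."""
    metrics = ["dsc", "iou", "precision", "recall",
               "dsc_foreground", "iou_foreground"]
    return table.groupby("preset")[metrics].agg(["mean", "std"])
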