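"""Training protocol: Adam on the hybrid Dice+BCE loss, reduce-LR-on-plateau
(factor 0.1, patience 10), early stopping after 15 non-improving epochs,
manifest splitting, and the five-configuration ablation harness
(baseline / +attention / +OSL / +feedback / full).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import dice, evaluate, hybrid_loss, hybrid_loss_tensor
from .network import ModelConfig, SegmentationNetwork, build_model
from .preprocess import AugmentationConfig, augment_pair

__all__ = ["TrainConfig", "SplitSpec", "EpochRecord", "Adam",
           "PlateauScheduler", "EarlyStopper", "split_manifest", "train",
           "run_ablation", "ABLATION_LABELS"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 16
    max_epochs: int = 150
    lr_factor: float = 0.1
    lr_patience: int = 10
    early_stop_patience: int = 15
    min_delta: float = 1e-4
    min_lr: float = 1e-7
    w_dice: float = 0.5
    w_bce: float = 0.5
    bn_refresh_batches: int = 8
    seed: int = 0
    augment: Optional[AugmentationConfig] = None

    def __post_init__(self):
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    counts: tuple            # (train, val, test)
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.counts) or len(self.counts) != 3:
            raise ValueError("counts must be three nonnegative integers")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_accuracy: float
    val_loss: float
    val_accuracy: float
    val_dice: float
    lr: float


_SPLIT_NAMES = ("train", "val", "test")


def split_manifest(records, spec: SplitSpec) -> pd.DataFrame:
    """Seeded shuffle then contiguous split assignment.

    Records beyond the requested counts are labelled ``unused``; requested
    counts exceeding the manifest size raise.
    """
    df = pd.DataFrame(records).copy()
    total = sum(spec.counts)
    if total > len(df):
        raise ValueError(f"requested {total} records but manifest has {len(df)}")
    order = np.random.default_rng(spec.seed).permutation(len(df))
    labels = np.full(len(df), "unused", dtype=object)
    start = 0
    for name, count in zip(_SPLIT_NAMES, spec.counts):
        labels[order[start:start + count]] = name
        start += count
    df["split"] = labels
    return df


# ------------------------------------------------------------- optimization

class Adam:
    """Adam over a list of autodiff parameter tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class PlateauScheduler:
    """Multiply LR by ``factor`` after ``patience`` consecutive epochs
    without improvement (> min_delta) of the monitored validation loss."""

    def __init__(self, lr, factor=0.1, patience=10, min_delta=1e-4,
                 min_lr=1e-7):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.min_lr = min_lr
        self.best = np.inf
        self.counter = 0

    def step(self, val_loss) -> float:
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.counter = 0
        else:
            self.counter += 1
            if self.counter >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.counter = 0
        return self.lr


class EarlyStopper:
    """Signal stop after ``patience`` consecutive non-improving epochs."""

    def __init__(self, patience=15, min_delta=1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.counter = 0

    def step(self, val_loss) -> bool:
        """Returns True while training should continue."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.counter = 0
            return True
        self.counter += 1
        return self.counter < self.patience


# ------------------------------------------------------------------- train

def _pixel_accuracy(probs, masks, threshold=0.5):
    pred = probs >= threshold
    truth = masks > 0
    return float((pred == truth).mean())


def train(model: SegmentationNetwork, train_images, train_masks,
          val_images, val_masks, config: TrainConfig = TrainConfig(),
          verbose: bool = False) -> List[EpochRecord]:
    """Mini-batch Adam training with plateau LR decay and early stopping.

    ``*_images``: (N, H, W, 3) float arrays in [0, 1]; ``*_masks``:
    (N, H, W) binary.  Online augmentation, if configured, is applied to the
    training stream only.  The best-validation-loss weights are restored
    into the model before returning.
    """
    train_images = np.asarray(train_images, dtype=np.float32)
    train_masks = np.asarray(train_masks)
    val_images = np.asarray(val_images, dtype=np.float32)
    val_masks = np.asarray(val_masks)
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("training and validation sets must be nonempty")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr, beta1=config.beta1,
               beta2=config.beta2)
    sched = PlateauScheduler(config.lr, config.lr_factor, config.lr_patience,
                             config.min_delta, config.min_lr)
    stopper = EarlyStopper(config.early_stop_patience, config.min_delta)

    history: List[EpochRecord] = []
    best_loss = np.inf
    best_state = None
    n = len(train_images)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = train_images[idx]
            yb = (train_masks[idx] > 0).astype(np.float32)
            if config.augment is not None:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(idx)):
                    aug_seed = int(rng.integers(2 ** 31))
                    xb[j], yb[j] = augment_pair(xb[j], yb[j],
                                                config.augment, aug_seed)
            out = model.forward(xb, training=True)
            loss = hybrid_loss_tensor(out, yb[..., None], config.w_dice,
                                      config.w_bce)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.lr = sched.lr
            opt.step()
            losses.append(float(loss.data))
            accs.append(_pixel_accuracy(out.data[..., 0], yb))

        if config.bn_refresh_batches > 0:
            # re-estimate BN statistics (dropout off) on a deterministic,
            # evenly spaced training subsample before validating
            k = min(n, config.bn_refresh_batches * config.batch_size)
            idx = np.linspace(0, n - 1, k).astype(int)
            model.refresh_batchnorm(train_images[idx],
                                    batch_size=config.batch_size)
        val_probs = model.predict(val_images,
                                  batch_size=max(1, config.batch_size))
        val_loss = hybrid_loss(val_probs, val_masks, config.w_dice,
                               config.w_bce)
        val_acc = _pixel_accuracy(val_probs, val_masks)
        val_dice = float(np.mean([dice(p >= 0.5, m)
                                  for p, m in zip(val_probs, val_masks)]))
        lr_now = sched.step(val_loss)
        keep_going = stopper.step(val_loss)

        history.append(EpochRecord(
            epoch=epoch, train_loss=float(np.mean(losses)),
            train_accuracy=float(np.mean(accs)), val_loss=val_loss,
            val_accuracy=val_acc, val_dice=val_dice, lr=lr_now))
        if verbose:
            r = history[-1]
            print(f"epoch {r.epoch:3d}  train {r.train_loss:.4f}  "
                  f"val {r.val_loss:.4f}  val_dice {r.val_dice:.4f}  "
                  f"lr {r.lr:.2e}")

        if val_loss < best_loss:
            best_loss = val_loss
            best_state = copy.deepcopy(model.state_arrays())
        if not keep_going:
            break

    if best_state is not None:
        model.load_state_arrays(best_state)
    return history


def history_frame(history: Sequence[EpochRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in history])


# ---------------------------------------------------------------- ablation

ABLATION_LABELS = ("baseline", "+attention", "+osl", "+feedback", "full")


def _ablation_config(base: ModelConfig, label: str) -> ModelConfig:
    switches = {
        "baseline": dict(use_attention=False, use_osl=False, use_feedback=False),
        "+attention": dict(use_attention=True, use_osl=False, use_feedback=False),
        "+osl": dict(use_attention=False, use_osl=True, use_feedback=False),
        "+feedback": dict(use_attention=False, use_osl=False, use_feedback=True),
        "full": dict(use_attention=True, use_osl=True, use_feedback=True),
    }
    return replace(base, **switches[label])


def run_ablation(train_images, train_masks, val_images, val_masks,
                 base_config: ModelConfig, train_config: TrainConfig,
                 seed: int = 0, verbose: bool = False) -> pd.DataFrame:
    """Train and evaluate the five architectural configurations.

    All runs share the same data, seed and epoch budget; the result has one
    row per configuration with Dice, IoU, pixel accuracy and the parameter
    count.
    """
    rows = []
    for label in ABLATION_LABELS:
        cfg = _ablation_config(base_config, label)
        model = build_model(cfg, seed=seed)
        train(model, train_images, train_masks, val_images, val_masks,
              replace(train_config, seed=seed), verbose=verbose)
        report = evaluate(model, val_images, val_masks)
        rows.append({"configuration": label, "dice": report.dice,
                     "iou": report.iou, "accuracy": report.pixel_accuracy,
                     "n_params": model.count_parameters()})
    return pd.DataFrame(rows)
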