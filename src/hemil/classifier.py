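"""Residual patch classifier: backbone, patient-level split, training loop.

The backbone follows the 18-layer residual recipe: one stem convolution,
four stages of two basic blocks (two 3x3 convolutions each, identity or
1x1-projection skips, stride-2 downsampling at each stage transition after
the first), global average pooling and a two-way fully connected head —
so the weighted-layer count is ``1 + stages*blocks_per_stage*convs_per_block + 1``
(18 at the defaults).  Projection shortcuts and normalization layers are
not counted.

Training is plain SGD with momentum on cross-entropy, with the best
checkpoint selected by validation accuracy (first epoch achieving the
maximum).  Weights start from random initialization; a checkpoint path in
the config reproduces a transfer-learning regime when external weights
are available, and ``freeze_up_to_stage`` freezes the early stages.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

log = logging.getLogger(__name__)


class InvalidModelError(ValueError):
    """Model does not satisfy the backbone contract."""


class DivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


class StratificationError(ValueError):
    """Stratified split impossible (single-class cohort)."""


@dataclass
class BackboneConfig:
    stages: int = 4
    blocks_per_stage: int = 2
    convs_per_block: int = 2  # fixed by the basic-block design
    base_width: int = 64
    n_classes: int = 2
    pretrained_weights_path: str | None = None
    freeze_up_to_stage: int = 0  # 0 = train everything

    def __post_init__(self) -> None:
        if self.stages < 1 or self.blocks_per_stage < 1 or self.base_width < 1:
            raise ValueError("stages, blocks_per_stage and base_width must be positive")
        if self.convs_per_block != 2:
            raise ValueError("basic blocks contain exactly two convolutions")

    @property
    def weighted_layers(self) -> int:
        return 1 + self.stages * self.blocks_per_stage * self.convs_per_block + 1


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 25
    batch_size: int = 32
    split_ratio: float = 0.8
    split_unit: str = "patient"  # or "patch"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio must be in (0,1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.split_unit not in ("patient", "patch"):
            raise ValueError("split_unit must be 'patient' or 'patch'")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_accuracy: float
    val_accuracy: float
    is_best: bool = False


class Backbone:
    """Residual network wrapper exposing the layer list and metadata."""

    def __init__(self, config: BackboneConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.base_width
        layers: list[nn.Module] = [
            nn.Conv2d(3, w, 7, stride=2, pad=3, rng=rng, input_grad=False),
            nn.BatchNorm2d(w),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, 1),
        ]
        c_in = w
        for s in range(config.stages):
            c_out = w * (2 ** s)
            for b in range(config.blocks_per_stage):
                stride = 2 if (s > 0 and b == 0) else 1
                layers.append(nn.BasicBlock(c_in, c_out, stride, rng=rng))
                c_in = c_out
        self.last_block_index = len(layers) - 1  # Grad-CAM default target
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Linear(c_in, config.n_classes, rng=rng))
        self.net = nn.Sequential(layers)
        if config.freeze_up_to_stage > 0:
            self._freeze(config.freeze_up_to_stage)
        if config.pretrained_weights_path:
            self.load_weights(config.pretrained_weights_path)

    def _freeze(self, up_to_stage: int) -> None:
        for m in self.net.layers[:4]:
            m.frozen = True
        idx = 4
        for s in range(self.config.stages):
            for _ in range(self.config.blocks_per_stage):
                if s < up_to_stage:
                    self.net.layers[idx].frozen = True
                idx += 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train)

    def save_weights(self, path: str | Path, meta: dict | None = None) -> None:
        path = Path(path)
        np.savez(path, **self.net.state())
        sidecar = {"stages": self.config.stages,
                   "blocks_per_stage": self.config.blocks_per_stage,
                   "base_width": self.config.base_width,
                   "n_classes": self.config.n_classes}
        sidecar.update(meta or {})
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    def load_weights(self, path: str | Path) -> None:
        with np.load(path) as data:
            self.net.load_state({k: data[k] for k in data.files})


def build_backbone(config: BackboneConfig | None = None, seed: int = 0) -> Backbone:
    return Backbone(config or BackboneConfig(), seed=seed)


def count_weighted_layers(model: Backbone) -> int:
    """Count convolutional + fully connected layers, excluding normalization
    layers and projection shortcuts."""
    if not isinstance(model, Backbone):
        raise InvalidModelError("expected a Backbone")
    n_conv = n_fc = 0
    for m in model.net.layers:
        if isinstance(m, nn.Conv2d) and not m.is_projection:
            n_conv += 1
        elif isinstance(m, nn.Linear):
            n_fc += 1
        elif isinstance(m, nn.BasicBlock):
            for sm in m.submodules():
                if isinstance(sm, nn.Conv2d) and not sm.is_projection:
                    n_conv += 1
    if n_fc != 1:
        raise InvalidModelError("backbone must end in exactly one fully connected head")
    return n_conv + n_fc


def split_cohort(bags: list, config: TrainConfig):
    """Label-stratified train/validation split.

    At the default patient unit, whole bags go to one side only.  At the
    patch unit each patch is assigned independently (available for
    fidelity experiments; it leaks patients across the split).
    Deterministic given ``config.seed``.
    """
    if len(bags) < 2:
        raise ValueError("need at least 2 bags to split")
    labels = {b.label for b in bags}
    if len(labels) < 2:
        raise StratificationError("both classes must be present to stratify")
    rng = np.random.default_rng(config.seed)

    if config.split_unit == "patch":
        units = [(b, pid) for b in bags for pid in b.patch_ids]
        unit_labels = [b.label for b, _ in units]
    else:
        units = list(bags)
        unit_labels = [b.label for b in bags]

    train_idx: list[int] = []
    for lab in sorted(labels):
        idx = [i for i, ul in enumerate(unit_labels) if ul == lab]
        idx = list(rng.permutation(idx))
        n_train = int(round(config.split_ratio * len(idx)))
        train_idx.extend(idx[:n_train])
    train_set = set(train_idx)

    if config.split_unit == "patch":
        train_units = [units[i] for i in sorted(train_set)]
        val_units = [units[i] for i in range(len(units)) if i not in train_set]
        return train_units, val_units
    train_bags = [units[i] for i in sorted(train_set)]
    val_bags = [units[i] for i in range(len(units)) if i not in train_set]
    return train_bags, val_bags


def _batched_eval(model: Backbone, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(model.forward(x[i:i + batch_size], train=False))
    return np.concatenate(outs, axis=0)


def train(model: Backbone, train_x: np.ndarray, train_y: np.ndarray,
          val_x: np.ndarray, val_y: np.ndarray, config: TrainConfig):
    """SGD-with-momentum training with best-checkpoint selection.

    ``train_x``/``val_x`` are normalized patch stacks (N,3,224,224); labels
    are 0 = low, 1 = high (inherited from each patch's bag).  Returns
    ``(best_model, records)`` where ``best_model`` carries the weights of
    the first epoch achieving the maximum validation accuracy.
    """
    if len(train_x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.net, lr=config.learning_rate, momentum=config.momentum)
    records: list[EpochRecord] = []
    best_acc = -1.0
    best_state = None
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_x))
        total_loss = 0.0
        correct = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = train_x[idx], train_y[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            total_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
        val_logits = _batched_eval(model, val_x)
        val_acc = float((val_logits.argmax(axis=1) == val_y).mean()) if len(val_x) else 0.0
        rec = EpochRecord(epoch=epoch,
                          train_loss=total_loss / len(train_x),
                          train_accuracy=correct / len(train_x),
                          val_accuracy=val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = copy.deepcopy(model.net.state())
            rec.is_best = True
        records.append(rec)
        log.info("epoch %d: loss %.4f train acc %.3f val acc %.3f%s", epoch,
                 rec.train_loss, rec.train_accuracy, val_acc,
                 " *" if rec.is_best else "")
    if best_state is not None:
        model.net.load_state(best_state)
    return model, records


def predict_patch_probs(model: Backbone, x: np.ndarray,
                        batch_size: int = 64) -> np.ndarray:
    """Softmax probability of the positive ("high") class per patch."""
    if len(x) == 0:
        return np.zeros(0)
    logits = _batched_eval(model, x, batch_size)
    return nn.softmax(logits.astype(np.float64))[:, 1]
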