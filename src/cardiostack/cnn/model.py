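"""The 10-block convolutional classifier and its architecture audit."""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cardiostack.cnn.layers import (
    Adam,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2,
    ReLU,
    cross_entropy,
    softmax,
)

__all__ = ["CnnConfig", "Cnn", "build_model", "DEFAULT_CHANNELS", "TINY_CHANNELS"]

# Doubling at each pooled block, 16 -> 256; the published figure's exact
# widths are not available, so this profile is configurable.
DEFAULT_CHANNELS = (16, 16, 16, 32, 32, 64, 64, 64, 128, 256)
TINY_CHANNELS = (2, 2, 2, 4, 4, 4, 4, 4, 8, 8)

N_BLOCKS = 10
BN_BLOCKS = (1, 10)  # 1-indexed
POOL_BLOCKS = (4, 6, 9, 10)


@dataclass
class CnnConfig:
    input_shape: tuple[int, int]  # (H, W); single-channel input
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    kernel_size: int = 3
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    mixup_alpha: float = 0.2
    spec_augment_masks: int = 2
    freq_mask_width: int = 16
    time_mask_width: int = 24

    def __post_init__(self) -> None:
        if len(self.channels) != N_BLOCKS:
            raise ValueError(f"exactly {N_BLOCKS} convolution blocks are required, got {len(self.channels)}")
        h, w = self.input_shape
        if h < 16 or w < 16:
            raise ValueError("input must be at least 16 x 16 to survive four 2x2 poolings")

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "channels": list(self.channels),
            "kernel_size": self.kernel_size,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }


class Cnn:
    """10 conv blocks (conv -> [BN] -> ReLU -> [pool]) -> global avg pool -> softmax(2)."""

    def __init__(self, config: CnnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks: list[list] = []
        c_in = 1
        for b in range(1, N_BLOCKS + 1):
            c_out = config.channels[b - 1]
            block = [Conv2d(c_in, c_out, config.kernel_size, rng)]
            if b in BN_BLOCKS:
                block.append(BatchNorm2d(c_out))
            block.append(ReLU())
            if b in POOL_BLOCKS:
                block.append(MaxPool2())
            self.blocks.append(block)
            c_in = c_out
        self.global_pool = GlobalAvgPool()
        self.head = Linear(c_in, 2, rng)
        self._layers = [l for blk in self.blocks for l in blk] + [self.global_pool, self.head]

    # -- forward / backward -------------------------------------------------

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2:] != tuple(self.config.input_shape):
            raise ValueError(f"input shape {x.shape[2:]} does not match configured {self.config.input_shape}")
        out = x.astype(np.float32)
        for layer in self._layers:
            out = layer.forward(out, train)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-item 2-vectors of nonnegative reals summing to 1."""
        return softmax(self.logits(x, train))

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Positive-class probability per item, evaluation mode."""
        out = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = self.forward(np.asarray(x[i : i + batch_size]))[:, 1]
        return out

    def train_step(self, x: np.ndarray, soft_labels: np.ndarray, optimizer: Adam) -> float:
        probs = softmax(self.logits(x, train=True))
        loss, grad = cross_entropy(probs, soft_labels.astype(np.float32))
        for layer in reversed(self._layers):
            grad = layer.backward(grad)
        optimizer.step()
        return loss

    def make_optimizer(self) -> Adam:
        params, grads = [], []
        for layer in self._layers:
            params.extend(layer.params())
            grads.extend(layer.grads())
        return Adam(params, grads, lr=self.config.learning_rate)

    # -- introspection / persistence ---------------------------------------

    def audit(self) -> dict:
        """Walk the layer graph and report the architectural skeleton."""
        conv_count = 0
        bn_blocks, pool_blocks = [], []
        for bi, block in enumerate(self.blocks, start=1):
            for layer in block:
                if isinstance(layer, Conv2d):
                    conv_count += 1
                elif isinstance(layer, BatchNorm2d):
                    bn_blocks.append(bi)
                elif isinstance(layer, MaxPool2):
                    pool_blocks.append(bi)
        return {
            "n_conv": conv_count,
            "bn_blocks": bn_blocks,
            "pool_blocks": pool_blocks,
            "head": "global_avg_pool + linear(2) + softmax",
            "output_dim": 2,
        }

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers:
            out.extend(copy.deepcopy(layer.params()))
            if isinstance(layer, BatchNorm2d):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer in self._layers:
            for p in layer.params():
                p[...] = state[i]
                i += 1
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[i]
                layer.running_var[...] = state[i + 1]
                i += 2

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.state())
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"config": self.config.to_dict(), "architecture": self.audit()}, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "Cnn":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        cfg_d = meta["config"]
        cfg = CnnConfig(
            input_shape=tuple(cfg_d["input_shape"]),
            channels=tuple(cfg_d["channels"]),
            kernel_size=cfg_d["kernel_size"],
            epochs=cfg_d["epochs"],
            batch_size=cfg_d["batch_size"],
            learning_rate=cfg_d["learning_rate"],
            seed=cfg_d["seed"],
        )
        model = cls(cfg)
        data = np.load(path.with_suffix(".npz"))
        model.load_state([data[k] for k in data.files])
        return model


def build_model(config: CnnConfig) -> Cnn:
    return Cnn(config)
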