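"""Densely connected convolutional regression network.

Stem convolution + average pool, a sequence of dense blocks separated by
channel-compressing transition layers, global average pooling and a
linear scalar head.  The net operates on normalized NHWC float32 batches
and returns an unclamped continuous score; clamping to the score range
happens at inference, not in the loss.
"""

from __future__ import annotations

import copy
import json

import numpy as np

from .layers import (
    DTYPE,
    AvgPool2,
    Conv2d,
    DenseBlock,
    GlobalAvgPool,
    Linear,
    ReLU,
    Transition,
)


class ConfigurationError(ValueError):
    """Network layout incompatible with the input size."""


class DenseRegressorNet:
    """Assembled network; deterministic initialization under the seed."""

    def __init__(self, config):
        self.config = config
        layout = tuple(config.dense_block_layout)
        n_halvings = 1 + (len(layout) - 1)   # stem pool + transitions
        if config.input_size % (2 ** n_halvings) or \
           config.input_size // (2 ** n_halvings) < 2:
            raise ConfigurationError(
                f"input size {config.input_size} incompatible with "
                f"{len(layout)} dense blocks")
        rng = np.random.default_rng(config.seed)
        self.stem = Conv2d(3, config.stem_channels, 3, rng)
        self.stem_relu = ReLU()
        self.stem_pool = AvgPool2()
        self.blocks: list[DenseBlock] = []
        self.transitions: list[Transition] = []
        c = config.stem_channels
        for i, n_layers in enumerate(layout):
            block = DenseBlock(c, n_layers, config.growth_rate, rng)
            self.blocks.append(block)
            c = block.cout
            if i < len(layout) - 1:
                tr = Transition(c, config.compression, rng)
                self.transitions.append(tr)
                c = tr.cout
        self.gap = GlobalAvgPool()
        self.head = Linear(c, 1, rng)
        self.feature_channels = c

    # -- parameters -------------------------------------------------------

    def param_layers(self) -> list:
        out = [self.stem]
        for b in self.blocks:
            out.extend(b.children)
        for t in self.transitions:
            out.extend(t.children)
        out.append(self.head)
        return out

    @property
    def n_params(self) -> int:
        return int(sum(v.size for l in self.param_layers()
                       for v in l.params.values()))

    def get_weights(self) -> list:
        return [copy.deepcopy(l.params) for l in self.param_layers()]

    def set_weights(self, weights: list) -> None:
        for layer, w in zip(self.param_layers(), weights):
            for k in layer.params:
                layer.params[k][...] = w[k]

    def zero_grad(self) -> None:
        for layer in self.param_layers():
            layer.zero_grad()

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: normalized (N, H, W, 3) float; returns (N,) raw scores."""
        x = np.ascontiguousarray(x, DTYPE)
        h = self.stem_pool.forward(
            self.stem_relu.forward(self.stem.forward(x)))
        self._block_acts: list[np.ndarray] = []
        for i, block in enumerate(self.blocks):
            h = block.forward(h)
            self._block_acts.append(h)
            if i < len(self.transitions):
                h = self.transitions[i].forward(h)
        h = self.gap.forward(h)
        return self.head.forward(h)[:, 0]

    def backward(self, dout: np.ndarray,
                 capture_block: int | None = None) -> np.ndarray | None:
        """Backprop d(loss)/d(score); optionally capture the gradient at
        a dense block's output (for Grad-CAM).  Returns that gradient."""
        d = self.head.backward(np.asarray(dout, DTYPE)[:, None])
        d = self.gap.backward(d)
        captured = None
        n_blocks = len(self.blocks)
        if capture_block is not None:
            capture_block = capture_block % n_blocks
        for i in range(n_blocks - 1, -1, -1):
            if i < len(self.transitions):
                d = self.transitions[i].backward(d)
            if capture_block == i:
                captured = d.copy()
            d = self.blocks[i].backward(d)
        d = self.stem.backward(
            self.stem_relu.backward(self.stem_pool.backward(d)))
        return captured

    def block_activation(self, idx: int) -> np.ndarray:
        return self._block_acts[idx % len(self.blocks)]

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint with the config embedded (npz + JSON header)."""
        from dataclasses import asdict
        arrays = {}
        for i, layer in enumerate(self.param_layers()):
            for k, v in layer.params.items():
                arrays[f"l{i}:{k}"] = v
        cfg = asdict(self.config)
        cfg["dense_block_layout"] = list(cfg["dense_block_layout"])
        arrays["config_json"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8)
        np.savez(str(path), **arrays)

    @staticmethod
    def load(path) -> "DenseRegressorNet":
        from ..config import RegressorConfig
        data = np.load(str(path))
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        cfg_dict["dense_block_layout"] = tuple(cfg_dict["dense_block_layout"])
        net = DenseRegressorNet(RegressorConfig(**cfg_dict))
        for i, layer in enumerate(net.param_layers()):
            for k in layer.params:
                layer.params[k][...] = data[f"l{i}:{k}"]
        return net
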