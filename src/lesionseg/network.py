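"""Attention-gated encoder-decoder segmentation network with order-statistics
bottleneck and iterative decoder feedback.

Topology (defaults): two encoder blocks (32, 64 filters, each two 3x3
convolutions + ReLU, then 2x2 max pool), a 128-filter bottleneck whose
second convolution consumes the order-statistics-augmented tensor (C+2
channels), and two decoder blocks (64, 32 filters) that upsample, gate the
matching encoder skip with additive attention, concatenate, and apply two
conv-BN-ReLU stages plus a final convolution with dropout.  A 1x1
convolution + sigmoid head emits per-pixel lesion probabilities.

Feedback: the forward pass may run T >= 1 times; pass t > 1 concatenates the
previous pass's decoder-block outputs (projected to a small channel budget
by a 1x1 convolution) into the matching decoder block.  Pass 1 uses zeros,
so a single pass is exactly the feedback-free computation.  Gradients flow
through all passes.

Every architectural element (attention, OSL, feedback) can be switched off
independently; all switches off yields a plain U-Net baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .osl import OSLParams, osl_layer

__all__ = ["ModelConfig", "SegmentationNetwork", "build_model",
           "encoder_block_shapes"]


@dataclass(frozen=True)
class ModelConfig:
    encoder_filters: tuple = (32, 64)
    bottleneck_filters: int = 128
    use_attention: bool = True
    use_osl: bool = True
    use_feedback: bool = True
    feedback_passes: int = 2
    feedback_channels: int = 8
    dropout_rate: float = 0.3
    osl_k: int = 1
    osl_eps: float = 1e-7
    input_size: int = 256

    def __post_init__(self):
        if self.feedback_passes < 1:
            raise ValueError("feedback_passes must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if any(f <= 0 for f in self.encoder_filters) or self.bottleneck_filters <= 0:
            raise ValueError("filter counts must be positive")
        if self.use_osl and self.osl_k > self.bottleneck_filters:
            raise ValueError(
                f"OSL k={self.osl_k} exceeds bottleneck channels "
                f"{self.bottleneck_filters}")
        stride = 2 ** len(self.encoder_filters)
        if self.input_size % stride:
            raise ValueError(f"input_size must be divisible by {stride}")

    @property
    def osl(self) -> OSLParams:
        return OSLParams(k=self.osl_k, eps=self.osl_eps)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_filters"] = list(self.encoder_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder_filters"] = tuple(d["encoder_filters"])
        return cls(**d)


# ------------------------------------------------------------------ layers

class Conv2D:
    """3x3 (or 1x1) stride-1 'same' convolution with He-normal init."""

    def __init__(self, cin, cout, k, rng, name=""):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = ad.Tensor(rng.normal(0.0, std, (k, k, cin, cout)),
                           requires_grad=True)
        self.b = ad.Tensor(np.zeros(cout), requires_grad=True)
        self.name = name

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]

    def n_params(self):
        return self.w.data.size + self.b.data.size


class BatchNorm2D:
    """Batch normalization with per-feedback-pass running statistics.

    The iterative decoder sends activations through the same layer once per
    feedback pass, and the activation statistics differ between passes (pass
    one sees zero feedback features).  A single running estimate would mix
    the passes and match neither at evaluation time, so each pass index
    keeps its own running mean/variance; the affine parameters are shared.
    """

    def __init__(self, c, name=""):
        self.gamma = ad.Tensor(np.ones(c), requires_grad=True)
        self.beta = ad.Tensor(np.zeros(c), requires_grad=True)
        self.channels = c
        self.running = {}            # pass index -> [mean, var]
        self.name = name
        self._cumulative_counts = None

    def _buffers(self, pass_idx):
        if pass_idx not in self.running:
            if not pass_idx and self.running:
                pass_idx = max(self.running)   # eval beyond trained passes
            else:
                self.running[pass_idx] = [
                    np.zeros(self.channels, dtype=np.float32),
                    np.ones(self.channels, dtype=np.float32)]
        return self.running[pass_idx]

    def start_cumulative(self):
        """Begin exact cumulative-average estimation of running stats."""
        self._cumulative_counts = {}
        self.running = {}

    def stop_cumulative(self):
        self._cumulative_counts = None

    def __call__(self, x, training, pass_idx=0):
        mean, var = self._buffers(pass_idx)
        if training and self._cumulative_counts is not None:
            cnt = self._cumulative_counts.get(pass_idx, 0)
            momentum = 1.0 / (cnt + 1)
            self._cumulative_counts[pass_idx] = cnt + 1
        else:
            momentum = 0.1
        return ad.batchnorm(x, self.gamma, self.beta, mean, var, training,
                            momentum=momentum)

    def parameters(self):
        return [self.gamma, self.beta]

    def n_params(self):
        return self.gamma.data.size + self.beta.data.size


class EncoderBlock:
    """Two 3x3 conv + ReLU stages, then 2x2 max pool."""

    def __init__(self, cin, filters, rng, name=""):
        self.conv1 = Conv2D(cin, filters, 3, rng, f"{name}.conv1")
        self.conv2 = Conv2D(filters, filters, 3, rng, f"{name}.conv2")

    def __call__(self, x):
        h, w = x.shape[1], x.shape[2]
        if h % 2 or w % 2:
            raise ValueError(f"encoder requires even spatial dims, got {h}x{w}")
        skip = ad.relu(self.conv2(ad.relu(self.conv1(x))))
        return skip, ad.maxpool2(skip)

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()


class AttentionGate:
    """Additive attention: alpha = sigmoid(psi(ReLU(theta(x) + phi(up(g)))))."""

    def __init__(self, skip_ch, gate_ch, rng, name=""):
        inter = max(1, skip_ch // 2)
        self.theta = Conv2D(skip_ch, inter, 1, rng, f"{name}.theta")
        self.phi = Conv2D(gate_ch, inter, 1, rng, f"{name}.phi")
        self.psi = Conv2D(inter, 1, 1, rng, f"{name}.psi")

    def __call__(self, x, g):
        g_up = ad.upsample2(g)
        if g_up.shape[1:3] != x.shape[1:3]:
            raise ValueError(f"gating signal {g_up.shape[2:]} does not match "
                             f"skip {x.shape[2:]} after resampling")
        alpha = ad.sigmoid(self.psi(ad.relu(ad.add(self.theta(x), self.phi(g_up)))))
        return ad.mul(x, alpha), alpha

    def parameters(self):
        return (self.theta.parameters() + self.phi.parameters()
                + self.psi.parameters())


class DecoderBlock:
    """Upsample + gated-skip (+ feedback) concat, two conv-BN-ReLU stages,
    final conv + ReLU + dropout."""

    def __init__(self, cin, skip_ch, fb_ch, filters, rng, name=""):
        self.upconv = Conv2D(cin, filters, 3, rng, f"{name}.up")
        y_ch = filters + skip_ch + fb_ch
        self.w1 = Conv2D(y_ch, filters, 3, rng, f"{name}.w1")
        self.bn1 = BatchNorm2D(filters, f"{name}.bn1")
        self.w2 = Conv2D(filters, filters, 3, rng, f"{name}.w2")
        self.bn2 = BatchNorm2D(filters, f"{name}.bn2")
        self.wf = Conv2D(filters, filters, 3, rng, f"{name}.wf")
        self.fb_ch = fb_ch

    def __call__(self, x, skip, fb, dropout_rate, rng, training,
                 pass_idx=0):
        up = ad.relu(self.upconv(ad.upsample2(x)))
        if up.shape[1:3] != skip.shape[1:3]:
            raise ValueError("decoder/skip spatial mismatch")
        parts = [up, skip] if fb is None else [up, skip, fb]
        y = ad.concat(parts, axis=-1)
        y1 = ad.relu(self.bn1(self.w1(y), training, pass_idx))
        y2 = ad.relu(self.bn2(self.w2(y1), training, pass_idx))
        out = ad.relu(self.wf(y2))
        return ad.dropout(out, dropout_rate, rng, training)

    def parameters(self):
        return (self.upconv.parameters() + self.w1.parameters()
                + self.bn1.parameters() + self.w2.parameters()
                + self.bn2.parameters() + self.wf.parameters())


# ------------------------------------------------------------------- model

class SegmentationNetwork:
    """Assembled encoder-decoder with switchable attention/OSL/feedback."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.default_rng(seed + 1).integers(2 ** 31))

        cf = config
        self.encoders = []
        cin = 3
        for i, f in enumerate(cf.encoder_filters):
            self.encoders.append(EncoderBlock(cin, f, rng, f"enc{i}"))
            cin = f

        self.bott_conv1 = Conv2D(cin, cf.bottleneck_filters, 3, rng, "bott1")
        bott2_in = cf.bottleneck_filters + (2 if cf.use_osl else 0)
        self.bott_conv2 = Conv2D(bott2_in, cf.bottleneck_filters, 3, rng, "bott2")

        self.decoder_filters = tuple(reversed(cf.encoder_filters))
        fb_ch = cf.feedback_channels if cf.use_feedback else 0
        self.decoders, self.gates, self.fb_projs = [], [], []
        x_ch = cf.bottleneck_filters
        for i, f in enumerate(self.decoder_filters):
            skip_ch = cf.encoder_filters[-(i + 1)]
            if cf.use_attention:
                self.gates.append(AttentionGate(skip_ch, x_ch, rng, f"gate{i}"))
            else:
                self.gates.append(None)
            self.decoders.append(
                DecoderBlock(x_ch, skip_ch, fb_ch, f, rng, f"dec{i}"))
            if cf.use_feedback:
                self.fb_projs.append(Conv2D(f, fb_ch, 1, rng, f"fbproj{i}"))
            else:
                self.fb_projs.append(None)
            x_ch = f

        self.head = Conv2D(x_ch, 1, 1, rng, "head")
        self._bn_refreshing = False

    # -- plumbing ----------------------------------------------------------

    def parameters(self):
        ps = []
        for enc in self.encoders:
            ps += enc.parameters()
        ps += self.bott_conv1.parameters() + self.bott_conv2.parameters()
        for gate, dec, proj in zip(self.gates, self.decoders, self.fb_projs):
            if gate is not None:
                ps += gate.parameters()
            ps += dec.parameters()
            if proj is not None:
                ps += proj.parameters()
        ps += self.head.parameters()
        return ps

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self.batchnorm_layers()):
            for t, (mean, var) in bn.running.items():
                arrays[f"bn{i}_mean_p{t}"] = mean
                arrays[f"bn{i}_var_p{t}"] = var
        return arrays

    def load_state_arrays(self, arrays: dict):
        for i, p in enumerate(self.parameters()):
            src = arrays[f"param_{i}"]
            if src.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at param {i}")
            p.data = np.asarray(src, dtype=np.float32).copy()
        for i, bn in enumerate(self.batchnorm_layers()):
            bn.running = {}
            t = 0
            while f"bn{i}_mean_p{t}" in arrays:
                bn.running[t] = [
                    np.asarray(arrays[f"bn{i}_mean_p{t}"], np.float32).copy(),
                    np.asarray(arrays[f"bn{i}_var_p{t}"], np.float32).copy()]
                t += 1

    def save(self, path):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_arrays())
        meta = {"schema_version": "1", "config": self.config.to_dict()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "SegmentationNetwork":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig.from_dict(meta["config"]))
        with np.load(path.with_suffix(".npz")) as arrays:
            model.load_state_arrays(dict(arrays))
        return model

    # -- forward -----------------------------------------------------------

    def _as_input(self, images) -> ad.Tensor:
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[3] != 3:
            raise ValueError(f"expected (N, H, W, 3) input, got {arr.shape}")
        s = self.config.input_size
        if arr.shape[1] != s or arr.shape[2] != s:
            raise ValueError(f"expected {s}x{s} input, got "
                             f"{arr.shape[1]}x{arr.shape[2]}")
        return ad.Tensor(arr)

    def forward(self, images, training: bool = False,
                n_passes: Optional[int] = None) -> ad.Tensor:
        """Run the network; returns an (N, H, W, 1) probability tensor.

        ``n_passes`` overrides the configured feedback pass count; 1 is the
        exact feedback-free reduction (zero feedback features).
        """
        cf = self.config
        x0 = self._as_input(images) if not isinstance(images, ad.Tensor) else images
        passes = n_passes if n_passes is not None else (
            cf.feedback_passes if cf.use_feedback else 1)
        if passes < 1:
            raise ValueError("n_passes must be >= 1")

        prev_outputs = None
        out = None
        for pass_idx in range(passes):
            skips = []
            x = x0
            for enc in self.encoders:
                skip, x = enc(x)
                skips.append(skip)

            x = ad.relu(self.bott_conv1(x))
            if cf.use_osl:
                x = osl_layer(x, cf.osl)
            x = ad.relu(self.bott_conv2(x))

            level_outputs = []
            for i, dec in enumerate(self.decoders):
                skip = skips[-(i + 1)]
                gate = self.gates[i]
                gated = gate(skip, x)[0] if gate is not None else skip
                fb = None
                if cf.use_feedback:
                    if prev_outputs is None:
                        n = x.shape[0]
                        fb = ad.Tensor(np.zeros(
                            (n, skip.shape[1], skip.shape[2],
                             cf.feedback_channels), dtype=np.float32))
                    else:
                        fb = self.fb_projs[i](prev_outputs[i])
                rate = 0.0 if self._bn_refreshing else cf.dropout_rate
                x = dec(x, gated, fb, rate, self._dropout_rng, training,
                        pass_idx)
                level_outputs.append(x)
            prev_outputs = level_outputs
            out = ad.sigmoid(self.head(x))
        return out

    def batchnorm_layers(self):
        return [bn for dec in self.decoders for bn in (dec.bn1, dec.bn2)]

    def refresh_batchnorm(self, images, batch_size: int = 8):
        """Re-estimate batch-norm running statistics over ``images``.

        Runs forward passes in training mode with dropout disabled and a
        cumulative (exact-average) update, which removes the bias that
        dropout-active mini-batch statistics leave in the EMA estimates.
        """
        arr = np.asarray(images, dtype=np.float32)
        bns = self.batchnorm_layers()
        if not bns:
            return
        for bn in bns:
            bn.start_cumulative()
        self._bn_refreshing = True
        try:
            for i in range(0, len(arr), batch_size):
                self.forward(arr[i:i + batch_size], training=True)
        finally:
            self._bn_refreshing = False
            for bn in bns:
                bn.stop_cumulative()

    def predict(self, images, batch_size: int = 8) -> np.ndarray:
        """Evaluation-mode probabilities as an (N, H, W) float array."""
        arr = np.asarray(images, dtype=np.float32)
        single = arr.ndim == 3
        if single:
            arr = arr[None]
        outs = []
        for i in range(0, len(arr), batch_size):
            out = self.forward(arr[i:i + batch_size], training=False)
            outs.append(out.data[..., 0])
        probs = np.concatenate(outs, axis=0)
        return probs[0] if single else probs


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationNetwork:
    """Construct a seeded, reproducibly initialized network."""
    return SegmentationNetwork(config, seed=seed)


def encoder_block_shapes(input_size: int, filters: Sequence[int]):
    """Expected (skip, pooled) spatial sizes per encoder level."""
    sizes = []
    s = input_size
    for f in filters:
        sizes.append(((s, s, f), (s // 2, s // 2, f)))
        s //= 2
    return sizes
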