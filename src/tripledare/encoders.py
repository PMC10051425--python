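"""The dual-view context network.

Two encoders produce three encodings per window:

* ``e_mlp``  — a two-layer feed-forward encoder (16 hidden units by default)
  over the normalized handcrafted feature vector;
* ``e_cnn``  — an attention CNN over the raw [3 sensors, 3 axes, T] signal:
  one three-layer 1-D convolution stack per sensor, channel concatenation, a
  combined three-layer stack, then temporal soft attention (softmax-scored
  weighted average pooling over time);
* ``e_fused``— the concatenation (mlp, cnn), the joint-fusion encoding.

A prediction head (hidden width 32, LeakyReLU, then a sigmoid per label)
turns the fused encoding into independent per-label context probabilities.
The CNN is an approximation of attention-CNN context encoders from the HCR
literature; kernel size, channel counts and strides are configurable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import ModelConfig
from .nn import Conv1d, Linear, Module


def fuse(e_mlp, e_cnn):
    """Joint-fusion encoding: concatenation in fixed (mlp, cnn) order."""
    if isinstance(e_mlp, Tensor) or isinstance(e_cnn, Tensor):
        return ad.concat([ad.constant(e_mlp), ad.constant(e_cnn)], axis=-1)
    return np.concatenate([e_mlp, e_cnn], axis=-1)


class _SensorStack(Module):
    def __init__(self, channels, kernel, strides, rng, slope):
        self.slope = slope
        chans = [3] + list(channels)
        self.convs = [Conv1d(chans[i], chans[i + 1], kernel, rng, stride=strides[i])
                      for i in range(3)]

    def __call__(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = ad.leaky_relu(conv(x), self.slope)
        return x


class DualViewNet(Module):
    """MLP + attention-CNN encoders with a multi-label sigmoid head."""

    def __init__(self, n_features: int, n_labels: int, window_samples: int,
                 config: ModelConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        self.config = config or ModelConfig()
        self.n_features = n_features
        self.n_labels = n_labels
        self.window_samples = window_samples
        self.dtype = dtype
        cfg = self.config
        rng = np.random.default_rng([seed % (2 ** 31), 7])
        h = cfg.mlp_hidden
        self.mlp1 = Linear(n_features, h, rng, dtype)
        self.mlp2 = Linear(h, h, rng, dtype)
        self.sensor_stacks = [
            _SensorStack(cfg.cnn_channels, cfg.cnn_kernel, cfg.cnn_strides, rng,
                         cfg.leaky_slope)
            for _ in range(3)]
        chans = [3 * cfg.cnn_channels[-1]] + list(cfg.cnn_combined_channels)
        self.combined = [
            Conv1d(chans[i], chans[i + 1], cfg.cnn_kernel, rng,
                   stride=cfg.cnn_combined_strides[i])
            for i in range(3)]
        self.cnn_dim = cfg.cnn_combined_channels[-1]
        self.att = Linear(self.cnn_dim, 1, rng, dtype)
        self.head1 = Linear(h + self.cnn_dim, cfg.head_hidden, rng, dtype)
        self.head2 = Linear(cfg.head_hidden, n_labels, rng, dtype)
        self.norm_stats = None  # source-fitted feature stats, set by training
        # fail fast if the window is too short for the conv pyramid
        self._check_time_axis(window_samples)

    def _check_time_axis(self, T: int) -> None:
        k = self.config.cnn_kernel
        for s in self.config.cnn_strides + self.config.cnn_combined_strides:
            if T < k:
                raise ValueError(
                    f"window of {self.window_samples} samples is too short for "
                    f"kernel {k} with the configured strides")
            T = (T - k) // s + 1

    # -- encoders ----------------------------------------------------------
    def encode_mlp(self, features) -> Tensor:
        x = ad.constant(np.asarray(features, dtype=self.dtype)
                        if not isinstance(features, Tensor) else features)
        x = ad.leaky_relu(self.mlp1(x), self.config.leaky_slope)
        return ad.leaky_relu(self.mlp2(x), self.config.leaky_slope)

    def encode_cnn(self, raw, return_attention: bool = False):
        arr = raw.data if isinstance(raw, Tensor) else np.asarray(raw)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.shape[1:3] != (3, 3):
            raise ValueError("raw input must have shape [B, 3, 3, T]")
        # time-major layout [B, T, axes] keeps every conv a single matmul
        arr = arr.astype(self.dtype, copy=False).transpose(0, 1, 3, 2)
        slope = self.config.leaky_slope
        per_sensor = [stack(ad.constant(np.ascontiguousarray(arr[:, s])))
                      for s, stack in enumerate(self.sensor_stacks)]
        h = ad.concat(per_sensor, axis=2)                    # [B, T', 3*C]
        for conv in self.combined:
            h = ad.leaky_relu(conv(h), slope)
        if self.config.attention:
            scores = self.att(h)                             # [B, T'', 1]
            weights = ad.softmax(scores, axis=1)
            pooled = ad.sum_(ad.mul(h, weights), axis=1)
        else:
            weights = None
            pooled = ad.mean(h, axis=1)
        if return_attention:
            return pooled, weights
        return pooled

    def predict_logits(self, e_fused) -> Tensor:
        z = ad.leaky_relu(self.head1(ad.constant(e_fused)), self.config.leaky_slope)
        return self.head2(z)

    def predict_contexts(self, e_fused) -> Tensor:
        """Independent per-label probabilities in (0, 1)."""
        return ad.sigmoid(self.predict_logits(e_fused))

    def forward(self, features, raw) -> dict[str, Tensor]:
        e_mlp = self.encode_mlp(features)
        e_cnn = self.encode_cnn(raw)
        e_fused = fuse(e_mlp, e_cnn)
        logits = self.predict_logits(e_fused)
        return {"e_mlp": e_mlp, "e_cnn": e_cnn, "e_fused": e_fused,
                "logits": logits}

    # -- numpy convenience (no graph) ---------------------------------------
    def predict_numpy(self, features, raw, batch_size: int = 512):
        """Probabilities and fused embeddings as numpy, in evaluation batches."""
        probs, fused = [], []
        n = len(features)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            out = self.forward(features[sl], raw[sl])
            probs.append(ad.sigmoid(out["logits"]).data)
            fused.append(out["e_fused"].data)
        return np.concatenate(probs), np.concatenate(fused)

    def embed_numpy(self, features, raw, batch_size: int = 512):
        """All three encodings as numpy arrays."""
        outs = {"e_mlp": [], "e_cnn": [], "e_fused": []}
        n = len(features)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            out = self.forward(features[sl], raw[sl])
            for k in outs:
                outs[k].append(out[k].data)
        return {k: np.concatenate(v) for k, v in outs.items()}

    # -- checkpointing -------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = dict(n_features=self.n_features, n_labels=self.n_labels,
                    window_samples=self.window_samples,
                    config=self.config.model_dump())
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        if self.norm_stats is not None:
            arrays["norm_mean"] = self.norm_stats.mean
            arrays["norm_sd"] = self.norm_stats.sd
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DualViewNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(meta["n_features"], meta["n_labels"], meta["window_samples"],
                        ModelConfig.model_validate(meta["config"]))
            arrays = [data[f"p{i}"] for i in range(len(model.parameters()))]
            if "norm_mean" in data:
                from .features import NormalizationStats
                model.norm_stats = NormalizationStats(mean=data["norm_mean"],
                                                      sd=data["norm_sd"])
        model.load_state_arrays(arrays)
        return model
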