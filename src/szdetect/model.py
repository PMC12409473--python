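"""The channel-as-token Transformer seizure classifier.

A window of C electrode channels x L samples is treated as C tokens of L
features each. An input projection (MLP1, one linear map applied to every
channel row) lifts tokens to d_model; N identical post-norm encoder layers
mix them with multi-head self-attention; an output projection (MLP2, two
linear layers with a ReLU bottleneck) maps each token to the two class
logits, and the readout takes token 0's logits (default) or the mean over
tokens before the final softmax.

Because there is no positional encoding, the network is channel-agnostic:
any channel count >= 1 works without reconfiguration, and the class score
is invariant under permutation of the non-readout channels (token-0
readout) or any channel permutation (mean-pool readout).

The published configuration is d_model=1024, N=8 layers, h=8 heads
(d_k = d_v = 128), d_ff=1024; :func:`tiny_config` gives a CPU-scale preset
with the same structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import EncoderLayer, Linear, Module, Param, ReLU, scaled_dot_attention, softmax

__all__ = [
    "ModelConfig",
    "ClassScore",
    "ChannelTransformer",
    "TrainedModel",
    "tiny_config",
    "scaled_dot_attention",
]


@dataclass(frozen=True)
class ModelConfig:
    window_len: int = 100
    d_model: int = 1024
    n_layers: int = 8
    n_heads: int = 8
    d_ff: int = 1024
    mlp2_hidden: int = 128
    n_classes: int = 2
    readout: str = "token0"  # or "mean_pool"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError(f"d_model={self.d_model} must be divisible by n_heads={self.n_heads}")
        if min(self.window_len, self.d_model, self.n_layers, self.n_heads,
               self.d_ff, self.mlp2_hidden, self.n_classes) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.readout not in ("token0", "mean_pool"):
            raise ValueError(f"readout must be 'token0' or 'mean_pool', got {self.readout!r}")

    @property
    def d_k(self) -> int:
        """Per-head key/query (and value) size, d_model / h."""
        return self.d_model // self.n_heads

    @property
    def d_v(self) -> int:
        return self.d_k


def tiny_config(readout: str = "token0") -> ModelConfig:
    """Desk-scale preset for CPU training; same structure, small widths."""
    return ModelConfig(d_model=64, n_layers=2, n_heads=4, d_ff=64, mlp2_hidden=32, readout=readout)


@dataclass(frozen=True)
class ClassScore:
    p_nonseizure: float
    p_seizure: float

    def __post_init__(self) -> None:
        s = self.p_nonseizure + self.p_seizure
        if not (0 <= self.p_nonseizure <= 1 and 0 <= self.p_seizure <= 1 and abs(s - 1) < 1e-6):
            raise ValueError(f"not a probability pair: ({self.p_nonseizure}, {self.p_seizure})")


class ChannelTransformer(Module):
    """MLP1 -> N encoder layers -> MLP2 -> readout. Input (B, C, L)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.mlp1 = Linear(config.window_len, config.d_model, rng)
        self.layers = [
            EncoderLayer(config.d_model, config.n_heads, config.d_ff, rng)
            for _ in range(config.n_layers)
        ]
        self.mlp2_a = Linear(config.d_model, config.mlp2_hidden, rng)
        self.mlp2_act = ReLU()
        self.mlp2_b = Linear(config.mlp2_hidden, config.n_classes, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Windows (B, C, L) -> class logits (B, n_classes)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3:
            raise ValueError(f"expected (batch, channels, window_len), got shape {x.shape}")
        if x.shape[2] != self.config.window_len:
            raise ValueError(
                f"window has {x.shape[2]} columns but the model expects L={self.config.window_len}"
            )
        h = self.mlp1.forward(x)
        for layer in self.layers:
            h = layer.forward(h)
        tok = self.mlp2_b.forward(self.mlp2_act.forward(self.mlp2_a.forward(h)))  # B,C,n_cls
        self._n_tokens = tok.shape[1]
        if self.config.readout == "token0":
            return tok[:, 0, :]
        return tok.mean(axis=1)

    def backward(self, g_logits: np.ndarray) -> None:
        b, c = g_logits.shape[0], self._n_tokens
        g_tok = np.zeros((b, c, self.config.n_classes))
        if self.config.readout == "token0":
            g_tok[:, 0, :] = g_logits
        else:
            g_tok[:] = g_logits[:, np.newaxis, :] / c
        g = self.mlp2_a.backward(self.mlp2_act.backward(self.mlp2_b.backward(g_tok)))
        for layer in reversed(self.layers):
            g = layer.backward(g)
        self.mlp1.backward(g)

    # -- inference helpers ---------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        """Seizure/non-seizure probabilities, (n, 2), batched for memory."""
        x = np.asarray(x)
        out = np.empty((len(x), self.config.n_classes))
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = softmax(self.forward(x[i : i + batch_size]))
        return out

    def score_window(self, window: np.ndarray) -> ClassScore:
        """Single window (C, L) -> calibrated class probabilities."""
        p = self.predict_proba(np.asarray(window)[np.newaxis])[0]
        return ClassScore(p_nonseizure=float(p[0]), p_seizure=float(p[1]))

    # -- (de)serialization ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for i, p in enumerate(params):
            a = arrays[f"p{i}"]
            if a.shape != p.value.shape:
                raise ValueError(f"parameter {i}: shape {a.shape} != expected {p.value.shape}")
            p.value = np.array(a, dtype=np.float64)


@dataclass
class TrainedModel:
    """Config + learned parameters + the training/selection record."""

    config: ModelConfig
    network: ChannelTransformer
    record: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        return self.network.predict_proba(x, batch_size=batch_size)

    def score_window(self, window: np.ndarray) -> ClassScore:
        return self.network.score_window(window)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = json.dumps({"config": asdict(self.config), "record": self.record})
        np.savez(path, __meta__=np.array(meta), **self.network.state_arrays())
        # np.savez appends .npz when absent
        return path if path.suffix == ".npz" else Path(str(path) + ".npz")

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            config = ModelConfig(**meta["config"])
            net = ChannelTransformer(config, seed=0)
            net.load_state_arrays({k: f[k] for k in f.files if k != "__meta__"})
        return TrainedModel(config=config, network=net, record=meta["record"])
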