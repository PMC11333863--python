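"""The dual-stream CNN + self-attention fall classifier.

Two architecturally identical but independently weighted streams process
the accelerometer and gyroscope channels of a segment:

1. three 1D-convolution encoders (64 filters, kernel 3, stride 1, same
   padding); the first two are ReLU-activated and max-pooled by 2, the
   third feeds a global pooling layer, yielding a 64-D feature vector per
   segment (temporal lengths LoS -> LoS/2 -> LoS/4 -> 1);
2. a self-attention module with 64x64 query/key/value matrices that
   re-weights the feature vector (row-stochastic attention);
3. the two 64-D weighted vectors are concatenated to 128-D and classified
   by batch-norm -> dropout(0.5) -> FC(128->256, ReLU) -> FC(256->2) ->
   softmax over {ADL, fall}.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import layers as L

FEATURE_DIM = 64
N_CLASSES = 2
LABEL_NAMES = ("adl", "fall")  # class index 1 = fall (positive)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (weights live in the network object)."""

    feature_dim: int = FEATURE_DIM
    attention_mode: str = "vector"  # 'vector' | 'temporal'
    pooling: str = "avg"  # 'avg' | 'max'
    temperature: Optional[float] = None  # default sqrt(feature_dim)
    dropout: float = 0.5
    hidden_dim: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attention_mode not in ("vector", "temporal"):
            raise ValueError(f"attention_mode must be 'vector'|'temporal', got {self.attention_mode!r}")


@dataclass
class AttentionOutput:
    """Per-stream attention diagnostics: the re-weighted feature vectors and
    the row-stochastic attention matrices that produced them."""

    weighted: np.ndarray  # (n, 64)
    attention: np.ndarray  # (n, 64, 64) vector mode; (n, T, T) temporal mode


@dataclass
class Diagnostics:
    """Intermediate quantities a forward pass exposes for analysis."""

    pre_attention: Dict[str, np.ndarray] = field(default_factory=dict)  # stream -> (n, 64)
    post_attention: Dict[str, AttentionOutput] = field(default_factory=dict)


class _Stream:
    """One sensor stream: 3 conv encoders + global pooling + self-attention."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        d = cfg.feature_dim
        self.cfg = cfg
        self.conv1 = L.Conv1dSame(3, d, rng)
        self.relu1 = L.ReLU()
        self.pool1 = L.MaxPool2()
        self.conv2 = L.Conv1dSame(d, d, rng)
        self.relu2 = L.ReLU()
        self.pool2 = L.MaxPool2()
        self.conv3 = L.Conv1dSame(d, d, rng)
        self.gpool = L.GlobalPool(cfg.pooling)
        if cfg.attention_mode == "vector":
            self.attn = L.VectorSelfAttention(d, rng, cfg.temperature)
        else:
            self.attn = L.TemporalSelfAttention(d, rng, cfg.temperature)

    def encode(self, x: np.ndarray, train: bool) -> np.ndarray:
        """Conv encoders + global pooling -> (n, 64) pre-attention features."""
        h = self.conv1.forward(x, train)
        h = self.relu1.forward(h, train)
        h = self.pool1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.relu2.forward(h, train)
        h = self.pool2.forward(h, train)
        h = self.conv3.forward(h, train)  # no activation before global pooling
        self._pre_pool = h
        return self.gpool.forward(h, train)

    def forward(self, x: np.ndarray, train: bool) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (post-attention (n,64), pre-attention (n,64), attention)."""
        if self.cfg.attention_mode == "vector":
            pre = self.encode(x, train)
            post = self.attn.forward(pre, train)
        else:
            # attention over LoS/4 temporal positions, then global pooling
            h = self.conv1.forward(x, train)
            h = self.relu1.forward(h, train)
            h = self.pool1.forward(h, train)
            h = self.conv2.forward(h, train)
            h = self.relu2.forward(h, train)
            h = self.pool2.forward(h, train)
            h = self.conv3.forward(h, train)
            pre = h.mean(axis=1)  # diagnostic only
            post = self.gpool.forward(self.attn.forward(h, train), train)
        return post, pre, self.attn.last_attention

    def backward(self, dpost: np.ndarray) -> None:
        if self.cfg.attention_mode == "vector":
            d = self.attn.backward(dpost)
            d = self.gpool.backward(d)
        else:
            d = self.gpool.backward(dpost)
            d = self.attn.backward(d)
        d = self.conv3.backward(d)
        d = self.pool2.backward(d)
        d = self.relu2.backward(d)
        d = self.conv2.backward(d)
        d = self.pool1.backward(d)
        d = self.relu1.backward(d)
        self.conv1.backward(d)

    def layers(self) -> List[L.Layer]:
        return [self.conv1, self.conv2, self.conv3, self.attn]


class DualStreamNet:
    """The full classifier; owns all parameters and the normalization stats."""

    def __init__(self, config: ModelConfig = ModelConfig()) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.feature_dim
        self.acc_stream = _Stream(config, rng)
        self.gyro_stream = _Stream(config, rng)
        self.bn = L.BatchNorm(2 * d)
        self.dropout = L.Dropout(config.dropout)
        self.dropout.rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        self.fc1 = L.Dense(2 * d, config.hidden_dim, rng)
        self.relu = L.ReLU()
        self.fc2 = L.Dense(config.hidden_dim, N_CLASSES, rng)
        # per-channel input standardization (set from training data)
        self.norm_mean = np.zeros(6, dtype=L.DTYPE)
        self.norm_std = np.ones(6, dtype=L.DTYPE)

    # ------------------------------------------------------------------ utils
    def _named_layers(self) -> List[Tuple[str, L.Layer]]:
        out = []
        for sname, stream in (("acc", self.acc_stream), ("gyro", self.gyro_stream)):
            for lname, layer in zip(("conv1", "conv2", "conv3", "attn"), stream.layers()):
                out.append((f"{sname}.{lname}", layer))
        out += [("bn", self.bn), ("fc1", self.fc1), ("fc2", self.fc2)]
        return out

    def parameters(self) -> Dict[str, np.ndarray]:
        return {
            f"{name}.{pname}": arr
            for name, layer in self._named_layers()
            for pname, arr in layer.params.items()
        }

    def gradients(self) -> Dict[str, np.ndarray]:
        return {
            f"{name}.{pname}": layer.grads.get(pname, np.zeros_like(arr))
            for name, layer in self._named_layers()
            for pname, arr in layer.params.items()
        }

    def n_parameters(self) -> int:
        return sum(arr.size for arr in self.parameters().values())

    def set_normalization(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.norm_mean = np.asarray(mean, dtype=L.DTYPE).reshape(6)
        self.norm_std = np.maximum(np.asarray(std, dtype=L.DTYPE).reshape(6), 1e-6)

    def _normalize(self, acc: np.ndarray, gyro: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        acc = (np.asarray(acc, dtype=L.DTYPE) - self.norm_mean[:3]) / self.norm_std[:3]
        gyro = (np.asarray(gyro, dtype=L.DTYPE) - self.norm_mean[3:]) / self.norm_std[3:]
        return acc, gyro

    # ---------------------------------------------------------------- forward
    def forward(
        self, acc: np.ndarray, gyro: np.ndarray, train: bool = False
    ) -> Tuple[np.ndarray, Diagnostics]:
        """Run a batch through both streams and the head.

        ``acc``/``gyro``: (n, LoS, 3) arrays sharing LoS (LoS divisible
        by 4). Returns softmax probabilities (n, 2) with class 1 = fall,
        plus per-stream pre/post-attention diagnostics.
        """
        acc = np.atleast_3d(np.asarray(acc, dtype=L.DTYPE))
        gyro = np.atleast_3d(np.asarray(gyro, dtype=L.DTYPE))
        if acc.shape != gyro.shape:
            raise ValueError(f"stream shapes differ: acc {acc.shape} vs gyro {gyro.shape}")
        if acc.shape[1] % 4:
            raise ValueError(f"segment length {acc.shape[1]} must be divisible by 4")
        acc, gyro = self._normalize(acc, gyro)

        diag = Diagnostics()
        post_a, pre_a, attn_a = self.acc_stream.forward(acc, train)
        post_g, pre_g, attn_g = self.gyro_stream.forward(gyro, train)
        diag.pre_attention = {"acc": pre_a, "gyro": pre_g}
        diag.post_attention = {
            "acc": AttentionOutput(post_a, attn_a),
            "gyro": AttentionOutput(post_g, attn_g),
        }
        concat = np.concatenate([post_a, post_g], axis=1)
        h = self.bn.forward(concat, train)
        h = self.dropout.forward(h, train)
        h = self.fc1.forward(h, train)
        h = self.relu.forward(h, train)
        logits = self.fc2.forward(h, train)
        self._last_logits = logits
        return L.softmax(logits), diag

    def logits(self, acc: np.ndarray, gyro: np.ndarray, train: bool = False) -> np.ndarray:
        self.forward(acc, gyro, train)
        return self._last_logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc2.backward(dlogits)
        d = self.relu.backward(d)
        d = self.fc1.backward(d)
        d = self.dropout.backward(d)
        d = self.bn.backward(d)
        dim = self.config.feature_dim
        self.acc_stream.backward(d[:, :dim])
        self.gyro_stream.backward(d[:, dim:])

    def classify(self, concat: np.ndarray, train: bool = False) -> np.ndarray:
        """Run the classification head alone on (n, 128) concatenated
        features; returns softmax probabilities (n, 2). Dropout is active
        only in training mode; BN uses running statistics in eval mode."""
        concat = np.atleast_2d(np.asarray(concat, dtype=L.DTYPE))
        if concat.shape[1] != 2 * self.config.feature_dim:
            raise ValueError(
                f"expected {2 * self.config.feature_dim}-D input, got {concat.shape[1]}"
            )
        h = self.bn.forward(concat, train)
        h = self.dropout.forward(h, train)
        h = self.fc1.forward(h, train)
        h = self.relu.forward(h, train)
        return L.softmax(self.fc2.forward(h, train))

    def predict(self, acc: np.ndarray, gyro: np.ndarray) -> np.ndarray:
        """Predicted class indices (1 = fall) for a batch, eval mode."""
        probs, _ = self.forward(acc, gyro, train=False)
        return probs.argmax(axis=1)

    # ------------------------------------------------------------- checkpoint
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.parameters().items()}
        state["bn.running_mean"] = self.bn.running_mean.copy()
        state["bn.running_var"] = self.bn.running_var.copy()
        state["norm_mean"] = self.norm_mean.copy()
        state["norm_std"] = self.norm_std.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for key, arr in params.items():
            arr[...] = state[key]
        self.bn.running_mean = np.asarray(state["bn.running_mean"], dtype=L.DTYPE)
        self.bn.running_var = np.asarray(state["bn.running_var"], dtype=L.DTYPE)
        self.norm_mean = np.asarray(state["norm_mean"], dtype=L.DTYPE)
        self.norm_std = np.asarray(state["norm_std"], dtype=L.DTYPE)

    def save(self, path: str | Path) -> Path:
        """Save weights + architecture config as a single .npz checkpoint."""
        path = Path(path)
        state = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        cfg = json.dumps({"format_version": 1, "model": asdict(self.config)})
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **state)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "DualStreamNet":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            if cfg.get("format_version") != 1:
                raise ValueError(f"unsupported checkpoint format: {cfg.get('format_version')}")
            net = cls(ModelConfig(**cfg["model"]))
            state = {k.replace("__", "."): data[k] for k in data.files if k != "__config__"}
        net.load_state_dict(state)
        return net


def encode_stream(x: np.ndarray, stream: _Stream) -> np.ndarray:
    """Pre-attention 64-D features for (n, LoS, 3) input (eval mode)."""
    return stream.encode(np.asarray(x, dtype=L.DTYPE), train=False)


def self_attention(x: np.ndarray, attn: L.VectorSelfAttention) -> AttentionOutput:
    """Apply one stream's self-attention to (n, 64) features (eval mode)."""
    weighted = attn.forward(np.asarray(x, dtype=L.DTYPE), train=False)
    return AttentionOutput(weighted=weighted, attention=attn.last_attention)
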