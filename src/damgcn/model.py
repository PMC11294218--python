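"""The dual-attention graph-convolutional classifier.

Forward path: batch-normalized residual graph convolutions over the
electrode graph, a transformer encoder over electrode-channel tokens, a
transposed encoder over frequency-band tokens (scaled by a learnable,
softmax-normalized band gate), then a two-linear-layer classifier head.
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from damgcn.montage import ElectrodeGraph
from damgcn.nn import Adam, Parameter, Tensor

__all__ = [
    "ModelConfig",
    "DAMGCNModel",
    "ForwardTrace",
    "gelu",
    "cross_entropy",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the network; defaults follow the published table."""

    num_channels: int = 62
    num_bands: int = 5
    embedding_size: int = 64
    num_encoders: int = 2          # encoder layers per attention stage
    num_heads: int = 6
    dropout: float = 0.5
    classifier_hidden: int | None = None  # defaults to embedding_size
    num_classes: int = 3
    gcn_layers: int = 2
    use_gcn: bool = True
    use_dam: bool = True
    single_self_loop: bool = False
    double_activation: bool = False  # literal reading: GELU inside and after residual
    positional_embedding: bool = False

    def __post_init__(self) -> None:
        for name in (
            "num_channels", "num_bands", "embedding_size", "num_encoders",
            "num_heads", "num_classes", "gcn_layers",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.classifier_hidden is None:
            self.classifier_hidden = self.embedding_size
        if self.head_dim < 1:
            raise ValueError(
                f"embedding_size {self.embedding_size} too small for "
                f"{self.num_heads} heads"
            )

    @property
    def head_dim(self) -> int:
        # floor division: with E=64 and 6 heads each head is 10-dimensional
        # and the output projection maps heads*head_dim back to E
        return self.embedding_size // self.num_heads


@dataclass
class ForwardTrace:
    """Intermediate quantities recorded during a forward pass."""

    logits: np.ndarray
    channel_attention: np.ndarray | None = None  # (layers, heads, C, C), batch-avg
    band_attention: np.ndarray | None = None     # (layers, heads, F, F), batch-avg
    channel_attention_per_sample: np.ndarray | None = None  # (layers, B, heads, C, C)
    band_gate_proportions: np.ndarray | None = None  # (F,), sums to 1
    activations: dict = field(default_factory=dict)


def gelu(x: Tensor) -> Tensor:
    """Sigmoid-approximated GELU: ``x * sigmoid(1.702 x)``."""
    return x * (x * 1.702).sigmoid()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over softmax probabilities; labels are class ids."""
    labels = np.asarray(labels)
    n, k = logits.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    logp = logits.log_softmax(axis=-1)
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def predict(logits: np.ndarray | Tensor) -> np.ndarray:
    data = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    return data.argmax(axis=-1)


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> Parameter:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return Parameter(rng.uniform(-bound, bound, size=(fan_in, fan_out)))


class _Linear:
    def __init__(self, rng, d_in: int, d_out: int):
        self.w = _xavier(rng, d_in, d_out)
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self):
        return [self.w, self.b]


class _LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class _BatchNorm:
    """Normalization over the batch axis, one (gamma, beta) per feature cell.

    Training mode uses batch statistics and updates exponential running
    statistics; eval mode uses the running statistics.
    """

    def __init__(self, shape: tuple[int, ...], eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(shape))
        self.beta = Parameter(np.zeros(shape))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(shape)
        self.running_var = np.ones(shape)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            if x.shape[0] < 2:
                raise ValueError(
                    "batch normalization needs batch >= 2 in training mode; "
                    "use eval mode or a larger batch"
                )
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data[0]
            self.running_var = (1 - m) * self.running_var + m * var.data[0]
            return centered / (var + self.eps).sqrt() * self.gamma + self.beta
        xn = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xn * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class _EncoderLayer:
    """Post-norm transformer encoder layer with recorded attention maps."""

    def __init__(self, rng, cfg: ModelConfig):
        e, h, dk = cfg.embedding_size, cfg.num_heads, cfg.head_dim
        self.h, self.dk = h, dk
        # W_Q starts at zero so attention begins exactly uniform and its
        # direction is set by the loss gradient, not by init noise; W_K
        # nonzero keeps the saddle escapable.
        self.wq = Parameter(np.zeros((e, h * dk)))
        self.wk = _xavier(rng, e, h * dk)
        self.wv = _xavier(rng, e, h * dk)
        self.wo = _Linear(rng, h * dk, e)
        self.ln1 = _LayerNorm(e)
        self.ln2 = _LayerNorm(e)
        self.ff1 = _Linear(rng, e, 4 * e)
        self.ff2 = _Linear(rng, 4 * e, e)
        self.dropout = cfg.dropout

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator):
        b, t, e = x.shape
        h, dk = self.h, self.dk

        def split_heads(z: Tensor) -> Tensor:  # (B,T,h*dk) -> (B,h,T,dk)
            return z.reshape(b, t, h, dk).transpose(0, 2, 1, 3)

        q, k, v = split_heads(x @ self.wq), split_heads(x @ self.wk), split_heads(x @ self.wv)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dk))
        attn = scores.softmax(axis=-1)  # (B,h,T,T)
        attn_applied = attn
        if training and self.dropout > 0:
            attn_applied = attn.dropout(self.dropout, rng)
        z = (attn_applied @ v).transpose(0, 2, 1, 3).reshape(b, t, h * dk)
        out = self.wo(z)
        if training and self.dropout > 0:
            out = out.dropout(self.dropout, rng)
        x = self.ln1(x + out)
        ff = self.ff2(gelu(self.ff1(x)))
        if training and self.dropout > 0:
            ff = ff.dropout(self.dropout, rng)
        x = self.ln2(x + ff)
        return x, attn.data  # pre-dropout attention for interpretability

    def params(self):
        return (
            [self.wq, self.wk, self.wv]
            + self.wo.params()
            + self.ln1.params()
            + self.ln2.params()
            + self.ff1.params()
            + self.ff2.params()
        )


class DAMGCNModel:
    """Trainable model; all parameters live in plain NumPy arrays."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c, f, e = config.num_channels, config.num_bands, config.embedding_size

        if config.use_gcn:
            self.input_norm = _BatchNorm((c, f))
            self.gcn_weights = [_xavier(rng, f, f) for _ in range(config.gcn_layers)]

        if config.use_dam:
            # channel stage: tokens = channels, features = band vector
            self.channel_embed = _Linear(rng, f, e)
            self.channel_embed_norm = _LayerNorm(e)
            self.channel_encoders = [
                _EncoderLayer(rng, config) for _ in range(config.num_encoders)
            ]
            self.channel_unembed = _Linear(rng, e, f)
            # band stage: tokens = bands, features = channel vector
            self.band_embed = _Linear(rng, c, e)
            self.band_embed_norm = _LayerNorm(e)
            self.band_gate = Parameter(np.zeros(f))  # softmax -> uniform 1/F at init
            self.band_encoders = [
                _EncoderLayer(rng, config) for _ in range(config.num_encoders)
            ]
            if config.positional_embedding:
                self.channel_pos = Parameter(np.zeros((c, e)))
                self.band_pos = Parameter(np.zeros((f, e)))
            head_in = f * e
        else:
            head_in = c * f

        hidden = config.classifier_hidden
        self.fc1 = _Linear(rng, head_in, hidden)
        self.fc2 = _Linear(rng, hidden, config.num_classes)

    # -- parameter plumbing ---------------------------------------------------

    def parameters(self) -> list[Parameter]:
        cfg = self.config
        params: list[Parameter] = []
        if cfg.use_gcn:
            params += self.input_norm.params() + self.gcn_weights
        if cfg.use_dam:
            params += self.channel_embed.params() + self.channel_embed_norm.params()
            for enc in self.channel_encoders:
                params += enc.params()
            params += self.channel_unembed.params()
            params += self.band_embed.params() + self.band_embed_norm.params()
            params.append(self.band_gate)
            for enc in self.band_encoders:
                params += enc.params()
            if cfg.positional_embedding:
                params += [self.channel_pos, self.band_pos]
        params += self.fc1.params() + self.fc2.params()
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        if self.config.use_gcn:
            arrays["running_mean"] = self.input_norm.running_mean
            arrays["running_var"] = self.input_norm.running_var
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            src = arrays[f"param_{i}"]
            if src.shape != p.data.shape:
                raise ValueError(f"param_{i}: shape {src.shape} != {p.data.shape}")
            p.data = np.array(src, dtype=float)
        if self.config.use_gcn:
            self.input_norm.running_mean = np.array(arrays["running_mean"])
            self.input_norm.running_var = np.array(arrays["running_var"])

    def band_gate_proportions(self) -> np.ndarray:
        """Softmax of the band gate — the reported per-band weight proportions."""
        if not self.config.use_dam:
            raise ValueError("band gate absent: model built with use_dam=False")
        g = self.band_gate.data
        e = np.exp(g - g.max())
        return e / e.sum()

    # -- forward --------------------------------------------------------------

    def _gcn_block(self, x: Tensor, propagation: np.ndarray, training: bool) -> Tensor:
        x = self.input_norm(x, training)
        p = Tensor(propagation)
        for w in self.gcn_weights:
            h = p @ x @ w
            if self.config.double_activation:
                h = gelu(h)
            x = gelu(h + x)  # residual add, one activation after it
        return x

    def forward(
        self,
        features: np.ndarray,
        graph: ElectrodeGraph | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
        record_per_sample: bool = False,
    ) -> tuple[Tensor, ForwardTrace]:
        """Run the network; returns (logits tensor, trace).

        ``features`` is batch x channels x bands.  ``graph`` is required when
        the GCN block is enabled.  ``rng`` drives dropout in training mode.
        """
        cfg = self.config
        x = Tensor(np.asarray(features, dtype=float))
        if x.ndim != 3 or x.shape[1] != cfg.num_channels or x.shape[2] != cfg.num_bands:
            raise ValueError(
                f"features shape {x.shape} does not match config "
                f"(B, {cfg.num_channels}, {cfg.num_bands})"
            )
        if training and rng is None:
            rng = np.random.default_rng(0)
        trace = ForwardTrace(logits=np.empty(0))

        if cfg.use_gcn:
            if graph is None or graph.propagation is None:
                raise ValueError("GCN block requires a graph with a propagation matrix")
            if graph.propagation.shape[0] != cfg.num_channels:
                raise ValueError("graph size does not match num_channels")
            x = self._gcn_block(x, graph.propagation, training)
            trace.activations["gcn_out"] = x.data

        if cfg.use_dam:
            b = x.shape[0]
            # channel tokens
            y = self.channel_embed_norm(self.channel_embed(x))
            if cfg.positional_embedding:
                y = y + self.channel_pos
            ch_attn = []
            for enc in self.channel_encoders:
                y, attn = enc(y, training, rng)
                ch_attn.append(attn)
            trace.channel_attention = np.stack([a.mean(axis=0) for a in ch_attn])
            if record_per_sample:
                trace.channel_attention_per_sample = np.stack(ch_attn)
            # back to band space with a stage residual: band tokens must stay
            # dominated by their own band's content or the band stage loses
            # the band identity the gate and band attention are meant to weigh
            x = x + self.channel_unembed(y)  # (B, C, F)
            z = x.transpose(0, 2, 1)  # (B, F, C)
            z = self.band_embed_norm(self.band_embed(z))
            if cfg.positional_embedding:
                z = z + self.band_pos
            bd_attn = []
            for enc in self.band_encoders:
                z, attn = enc(z, training, rng)
                bd_attn.append(attn)
            trace.band_attention = np.stack([a.mean(axis=0) for a in bd_attn])
            # the gate scales band tokens where the scale survives: after the
            # final post-norm encoder layer-norm, directly feeding the
            # classifier (inside the encoder stack every layer-norm would
            # erase a per-token scale, leaving the gate without gradient)
            gate = self.band_gate.softmax(axis=-1)  # (F,)
            trace.band_gate_proportions = gate.data.copy()
            z = z * gate.reshape(1, cfg.num_bands, 1)
            flat = z.reshape(b, cfg.num_bands * cfg.embedding_size)
        else:
            flat = x.reshape(x.shape[0], cfg.num_channels * cfg.num_bands)

        h = gelu(self.fc1(flat))
        if training and cfg.dropout > 0:
            h = h.dropout(cfg.dropout, rng)
        logits = self.fc2(h)
        trace.logits = logits.data
        return logits, trace


# ---------------------------------------------------------------------------
# Checkpoints: single-file zip with JSON config + NPZ parameter arrays
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_model(model: DAMGCNModel, path) -> None:
    import io

    buf = io.BytesIO()
    np.savez(buf, **model.state_arrays())
    meta = {"version": _CHECKPOINT_VERSION, "config": asdict(model.config)}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2))
        zf.writestr("params.npz", buf.getvalue())


def load_model(path) -> DAMGCNModel:
    import io

    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        if meta.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        with np.load(io.BytesIO(zf.read("params.npz"))) as z:
            arrays = {k: z[k] for k in z.files}
    model = DAMGCNModel(ModelConfig(**meta["config"]))
    model.load_state_arrays(arrays)
    return model
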