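"""Transformer-based multiple-instance-learning risk model.

A patient is represented by a *bag* of tile feature vectors (no ordering, no
positional information). The model projects each tile feature to an embedding
space through a fully connected layer with ReLU, prepends a learnable CLS
token, runs the sequence through a stack of pre-norm transformer blocks
(multi-head self-attention + feed-forward, both with residual connections and
layer normalization), and reads the patient-level risk score off the final
CLS state through a small MLP head. Higher scores mean worse predicted
disease-free survival.

Because the bag is a set, the forward pass is permutation-invariant over
tiles up to floating-point accumulation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .nn import Adam, Tensor, concat

__all__ = ["ModelConfig", "BagScore", "MILRiskModel", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n_layers=0`` collapses the network to projection + head, a linear-ish
    surrogate whose gradients can be written down by hand; it is kept as an
    analytic oracle for tests, not as a practical model.
    """

    input_dim: int = 1024
    embed_dim: int = 512
    n_layers: int = 2
    n_heads: int = 8
    ffn_dim: int = 2048
    dropout: float = 0.1
    head_hidden: tuple = (256,)
    head_layernorm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % max(self.n_heads, 1) != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class BagScore:
    patient_id: str
    risk: float

    def __post_init__(self):
        if not np.isfinite(self.risk):
            raise ValueError(f"non-finite risk for patient {self.patient_id}")


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal draws re-sampled until within ±2 std (ViT-style token init)."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


class MILRiskModel:
    """Bag-of-tiles -> scalar risk. Parameters live in a flat name->Tensor dict."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, Tensor] = {}

        def linear(name, fan_in, fan_out):
            # Xavier-uniform weights, zero biases
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            p[f"{name}.w"] = Tensor(rng.uniform(-lim, lim, (fan_in, fan_out)), requires_grad=True)
            p[f"{name}.b"] = Tensor(np.zeros(fan_out), requires_grad=True)

        def layernorm(name, dim):
            p[f"{name}.g"] = Tensor(np.ones(dim), requires_grad=True)
            p[f"{name}.b"] = Tensor(np.zeros(dim), requires_grad=True)

        d = cfg.embed_dim
        linear("proj", cfg.input_dim, d)
        p["cls"] = Tensor(_trunc_normal(rng, (1, d)), requires_grad=True)
        for i in range(cfg.n_layers):
            layernorm(f"blk{i}.ln1", d)
            linear(f"blk{i}.q", d, d)
            linear(f"blk{i}.k", d, d)
            linear(f"blk{i}.v", d, d)
            linear(f"blk{i}.o", d, d)
            layernorm(f"blk{i}.ln2", d)
            linear(f"blk{i}.ff1", d, cfg.ffn_dim)
            linear(f"blk{i}.ff2", cfg.ffn_dim, d)
        layernorm("head.ln", d)
        dims = (d,) + tuple(cfg.head_hidden) + (1,)
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            linear(f"head.fc{i}", a, b)
        self.n_head_layers = len(dims) - 1
        self.params = p

    # -- building blocks ------------------------------------------------------
    def _linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.w"] + self.params[f"{name}.b"]

    def _layernorm(self, name: str, x: Tensor, eps: float = 1e-5) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        xn = (x - mu) * (var + eps) ** -0.5
        return xn * self.params[f"{name}.g"] + self.params[f"{name}.b"]

    def _attention(self, i: int, x: Tensor, training: bool, rng) -> Tensor:
        cfg = self.cfg
        n = x.shape[0]
        h, dh = cfg.n_heads, cfg.embed_dim // cfg.n_heads
        q = self._linear(f"blk{i}.q", x).reshape(n, h, dh).transpose(1, 0, 2)
        k = self._linear(f"blk{i}.k", x).reshape(n, h, dh).transpose(1, 0, 2)
        v = self._linear(f"blk{i}.v", x).reshape(n, h, dh).transpose(1, 0, 2)
        att = (q @ k.swap_last()) * (1.0 / np.sqrt(dh))          # (h, n, n)
        att = att.softmax(axis=-1)
        if training and cfg.dropout > 0:
            att = att.dropout(cfg.dropout, rng)
        out = (att @ v).transpose(1, 0, 2).reshape(n, cfg.embed_dim)
        return self._linear(f"blk{i}.o", out)

    def _block(self, i: int, x: Tensor, training: bool, rng) -> Tensor:
        a = self._attention(i, self._layernorm(f"blk{i}.ln1", x), training, rng)
        if training and self.cfg.dropout > 0:
            a = a.dropout(self.cfg.dropout, rng)
        x = x + a
        f = self._linear(f"blk{i}.ff1", self._layernorm(f"blk{i}.ln2", x)).relu()
        f = self._linear(f"blk{i}.ff2", f)
        if training and self.cfg.dropout > 0:
            f = f.dropout(self.cfg.dropout, rng)
        return x + f

    # -- forward passes -------------------------------------------------------
    def forward_tensor(self, feats: Tensor, training: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        """Risk score as a scalar Tensor; `feats` is (n_tiles, input_dim)."""
        if feats.ndim != 2 or feats.shape[1] != self.cfg.input_dim:
            raise ValueError(
                f"expected bag of shape (n, {self.cfg.input_dim}), got {feats.shape}")
        if training and self.cfg.dropout > 0 and rng is None:
            raise ValueError("training-mode forward with dropout needs an rng")
        for k, p in self.params.items():
            if not np.all(np.isfinite(p.data)):
                raise FloatingPointError(f"non-finite parameter {k}")
        x = self._linear("proj", feats).relu()
        if self.cfg.n_layers == 0:
            # linear surrogate: no attention, bag representation = mean tile
            # embedding (reduces to the tile embedding for a singleton bag)
            rep = x.mean(axis=0)
        else:
            x = concat([self.params["cls"], x], axis=0)
            for i in range(self.cfg.n_layers):
                x = self._block(i, x, training, rng)
            rep = x[0]
        h = rep.reshape(1, -1)
        if self.cfg.head_layernorm:
            h = self._layernorm("head.ln", h)
        for i in range(self.n_head_layers):
            h = self._linear(f"head.fc{i}", h)
            if i < self.n_head_layers - 1:
                h = h.relu()
        return h.reshape(())

    def forward(self, feats: np.ndarray, patient_id: str = "") -> BagScore:
        """Inference-mode score for one bag (dropout disabled)."""
        out = self.forward_tensor(Tensor(np.asarray(feats, dtype=np.float64)))
        return BagScore(patient_id=patient_id, risk=out.item())

    def tile_forward(self, tile_feat: np.ndarray) -> float:
        """Score of a single tile == forward on the singleton bag."""
        tile_feat = np.asarray(tile_feat, dtype=np.float64)
        if tile_feat.ndim != 1 or tile_feat.shape[0] != self.cfg.input_dim:
            raise ValueError(f"expected vector of length {self.cfg.input_dim}")
        return self.forward(tile_feat[None, :]).risk

    # -- parameter plumbing ---------------------------------------------------
    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k} in state dict")
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params, lr=lr)

    def regularizable(self):
        """Names of weights subject to L1/L2 (LayerNorm params, biases, CLS excluded)."""
        return [k for k in self.params if k.endswith(".w")]


def save_checkpoint(path, model: MILRiskModel, meta: dict | None = None) -> None:
    """Single-file checkpoint: parameters + config + pipeline provenance."""
    payload = {
        "config": dataclasses.asdict(model.cfg),
        "meta": meta or {},
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(payload).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[MILRiskModel, dict]:
    with np.load(path) as npz:
        payload = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        state = {k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")}
    cfg_dict = payload["config"]
    cfg_dict["head_hidden"] = tuple(cfg_dict["head_hidden"])
    model = MILRiskModel(ModelConfig(**cfg_dict))
    model.load_state_dict(state)
    return model, payload["meta"]
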