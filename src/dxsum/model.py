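"""Character-level Transformer encoder with cloze and selection heads.

The network is deliberately small: one-hot character tokens over a
100-symbol vocabulary embedded into a hidden size of 64, summed with learned
position embeddings (up to 1350 positions), passed through a 16-layer
post-norm Transformer encoder with 16 self-attention heads, and decoded by
two single affine heads: decoder A maps each position to 100 symbol logits
for masked-character reconstruction, decoder S maps each position to 2
logits (select / don't select) for extractive summarization.  The reference
configuration has under a million trainable parameters, two orders of
magnitude below a standard base-size bidirectional Transformer encoder
(108,523,714 parameters).

All tensors are float32; forward passes in evaluation mode are
deterministic given fixed weights.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class ModelConfig:
    """Encoder hyperparameters; defaults are the reference configuration."""

    n_layers: int = 16
    n_heads: int = 16
    hidden: int = 64
    vocab: int = 100
    max_positions: int = 1350
    ff_width: int | None = None  # defaults to 4 x hidden
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.n_heads < 1 or self.hidden < 1:
            raise ValueError("layers, heads and hidden must be positive")
        if self.hidden % self.n_heads != 0:
            raise ValueError("hidden must be divisible by n_heads")
        if self.ff_width is None:
            object.__setattr__(self, "ff_width", 4 * self.hidden)

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """A desk-scale configuration for tests and smoke runs.

        Dropout is off: these runs are far too short for regularization to
        pay for the optimization it costs.
        """
        base = dict(n_layers=2, n_heads=2, hidden=32, dropout=0.0)
        base.update(overrides)
        return cls(**base)


def _trunc_normal(rng: np.random.Generator, shape: tuple[int, ...],
                  scale: float = 0.02) -> np.ndarray:
    """Normal(0, scale) resampled into +-2 scale, as float32."""
    x = rng.standard_normal(shape)
    while True:
        bad = np.abs(x) > 2.0
        if not bad.any():
            break
        x[bad] = rng.standard_normal(bad.sum())
    return (scale * x).astype(np.float32)


CHECKPOINT_VERSION = 1


class CharTransformer:
    """The summarization network: embeddings, encoder stack, two heads."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, v, p, f = config.hidden, config.vocab, config.max_positions, config.ff_width
        P: dict[str, Tensor] = {}

        def param(name: str, shape: tuple[int, ...], init: str = "normal") -> None:
            if init == "zeros":
                data = np.zeros(shape, dtype=np.float32)
            elif init == "ones":
                data = np.ones(shape, dtype=np.float32)
            else:
                data = _trunc_normal(rng, shape)
            P[name] = Tensor(data, requires_grad=True)

        param("tok_emb", (v, h))
        param("pos_emb", (p, h))
        param("emb_ln_g", (h,), "ones")
        param("emb_ln_b", (h,), "zeros")
        for i in range(config.n_layers):
            for w in ("q", "k", "v", "o"):
                param(f"l{i}.{w}_w", (h, h))
                param(f"l{i}.{w}_b", (h,), "zeros")
            param(f"l{i}.attn_ln_g", (h,), "ones")
            param(f"l{i}.attn_ln_b", (h,), "zeros")
            param(f"l{i}.ff1_w", (h, f))
            param(f"l{i}.ff1_b", (f,), "zeros")
            param(f"l{i}.ff2_w", (f, h))
            param(f"l{i}.ff2_b", (h,), "zeros")
            param(f"l{i}.ffn_ln_g", (h,), "ones")
            param(f"l{i}.ffn_ln_b", (h,), "zeros")
        param("dec_a_w", (h, v))
        param("dec_a_b", (v,), "zeros")
        param("dec_s_w", (h, 2))
        param("dec_s_b", (2,), "zeros")
        self.params = P

    # -- forward pieces ----------------------------------------------------
    def embed(self, ids: list[int] | np.ndarray) -> Tensor:
        """Sum of token and position embeddings, one row per character."""
        ids = np.asarray(ids, dtype=np.intp)
        if ids.size > self.config.max_positions:
            raise ValueError(
                f"sequence length {ids.size} exceeds max_positions "
                f"{self.config.max_positions}"
            )
        tok = nn.take_rows(self.params["tok_emb"], ids)
        pos = nn.take_rows(self.params["pos_emb"], np.arange(ids.size))
        return tok + pos

    def encode_sequence(self, ids: list[int] | np.ndarray, train: bool = False,
                        rng: np.random.Generator | None = None) -> Tensor:
        """Run the full encoder stack; returns (length, hidden) states."""
        cfg = self.config
        rate = cfg.dropout if train else 0.0
        if rate > 0.0 and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        P = self.params
        d_head = cfg.hidden // cfg.n_heads
        scale = 1.0 / np.sqrt(d_head)

        x = self.embed(ids)
        x = nn.layer_norm(x, P["emb_ln_g"], P["emb_ln_b"])
        if rate > 0.0:
            x = nn.dropout(x, rate, rng)
        L = x.shape[0]
        for i in range(cfg.n_layers):
            # multi-head self-attention, post-norm residual
            q = (x @ P[f"l{i}.q_w"] + P[f"l{i}.q_b"]).reshape(L, cfg.n_heads, d_head).transpose(1, 0, 2)
            k = (x @ P[f"l{i}.k_w"] + P[f"l{i}.k_b"]).reshape(L, cfg.n_heads, d_head).transpose(1, 0, 2)
            v = (x @ P[f"l{i}.v_w"] + P[f"l{i}.v_b"]).reshape(L, cfg.n_heads, d_head).transpose(1, 0, 2)
            # dropout is applied to sublayer outputs only, not to the
            # (heads, L, L) attention matrix
            ctx = nn.attention(q, k, v, scale).transpose(1, 0, 2).reshape(L, cfg.hidden)
            out = ctx @ P[f"l{i}.o_w"] + P[f"l{i}.o_b"]
            if rate > 0.0:
                out = nn.dropout(out, rate, rng)
            x = nn.layer_norm(x + out, P[f"l{i}.attn_ln_g"], P[f"l{i}.attn_ln_b"])
            # position-wise feed-forward, post-norm residual
            ff = nn.gelu(x @ P[f"l{i}.ff1_w"] + P[f"l{i}.ff1_b"]) @ P[f"l{i}.ff2_w"] + P[f"l{i}.ff2_b"]
            if rate > 0.0:
                ff = nn.dropout(ff, rate, rng)
            x = nn.layer_norm(x + ff, P[f"l{i}.ffn_ln_g"], P[f"l{i}.ffn_ln_b"])
        return x

    def decoder_A(self, hidden_states: Tensor) -> Tensor:
        """Cloze head: (length, vocab) logits for symbol reconstruction."""
        return hidden_states @ self.params["dec_a_w"] + self.params["dec_a_b"]

    def decoder_S(self, hidden_states: Tensor) -> Tensor:
        """Selection head: (length, 2) logits for don't-select / select."""
        return hidden_states @ self.params["dec_s_w"] + self.params["dec_s_b"]

    # -- accounting --------------------------------------------------------
    def parameter_breakdown(self) -> dict[str, int]:
        groups = {"embeddings": 0, "encoder": 0, "decoder_a": 0, "decoder_s": 0}
        for name, p in self.params.items():
            if name.startswith("l"):
                groups["encoder"] += p.data.size
            elif name.startswith("dec_a"):
                groups["decoder_a"] += p.data.size
            elif name.startswith("dec_s"):
                groups["decoder_s"] += p.data.size
            else:
                groups["embeddings"] += p.data.size
        groups["total"] = sum(groups.values())
        return groups

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Write a checkpoint archive (config echo + all weights)."""
        meta = json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(self.config)})
        arrays = {name.replace(".", "__"): p.data for name, p in self.params.items()}
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "CharTransformer":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
            model = cls(ModelConfig(**meta["config"]))
            for name, p in model.params.items():
                p.data = z[name.replace(".", "__")].astype(np.float32)
        return model


def count_parameters(config: ModelConfig) -> tuple[int, dict[str, int]]:
    """Exact trainable-scalar count and per-component breakdown."""
    breakdown = CharTransformer(config).parameter_breakdown()
    return breakdown["total"], breakdown
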