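"""Compact bidirectional transformer encoder (NumPy, pre-LayerNorm).

The architecture mirrors the standard masked-language-model encoder
stack — token + learned positional embeddings, multi-head
self-attention with an additive padding mask, GELU feed-forward blocks,
residual connections — scaled down so that domain-adaptive pretraining
and fine-tuning run on a single CPU. The ``tiny`` profile (2 layers,
4 heads, width 64) is the test and desk-scale default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

NEG_INF = -1e9


@dataclass
class EncoderConfig:
    vocab_size: int
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    max_len: int = 512
    init_std: float = 0.02
    ln_eps: float = 1e-5

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


def tiny_config(vocab_size: int) -> EncoderConfig:
    """The 2-layer / 4-head / width-64 profile used for CPU-scale runs."""
    return EncoderConfig(vocab_size=vocab_size)


class TransformerEncoder:
    """Encoder returning last-hidden-state embeddings per token."""

    def __init__(self, config: EncoderConfig, seed: int = 0, params: dict[str, Tensor] | None = None):
        self.config = config
        if params is not None:
            self.params = params
            return
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, Tensor] = {}

        def w(name, *shape):
            p[name] = Tensor(rng.normal(0.0, c.init_std, shape), requires_grad=True)

        def zeros(name, *shape):
            p[name] = Tensor(np.zeros(shape), requires_grad=True)

        def ones(name, *shape):
            p[name] = Tensor(np.ones(shape), requires_grad=True)

        w("tok_emb", c.vocab_size, c.d_model)
        w("pos_emb", c.max_len, c.d_model)
        for i in range(c.n_layers):
            pre = f"layer{i}."
            for nm in ("wq", "wk", "wv", "wo"):
                w(pre + nm, c.d_model, c.d_model)
                zeros(pre + nm + "_b", c.d_model)
            w(pre + "ff1", c.d_model, c.d_ff)
            zeros(pre + "ff1_b", c.d_ff)
            w(pre + "ff2", c.d_ff, c.d_model)
            zeros(pre + "ff2_b", c.d_model)
            ones(pre + "ln1_g", c.d_model)
            zeros(pre + "ln1_b", c.d_model)
            ones(pre + "ln2_g", c.d_model)
            zeros(pre + "ln2_b", c.d_model)
        ones("lnf_g", c.d_model)
        zeros("lnf_b", c.d_model)
        self.params = p

    @property
    def hidden_size(self) -> int:
        return self.config.d_model

    # -- forward --------------------------------------------------------
    def forward(self, ids: np.ndarray, attention_mask: np.ndarray) -> Tensor:
        """Encode ``ids`` [B, T] under a 0/1 ``attention_mask`` [B, T].

        Returns the last hidden state [B, T, d] as a graph tensor, so
        gradients flow back into the encoder when it is fine-tuned.
        """
        ids = np.asarray(ids, dtype=np.int64)
        mask = np.asarray(attention_mask, dtype=np.float64)
        if ids.shape != mask.shape:
            raise ValueError("ids and attention_mask shapes differ")
        B, T = ids.shape
        c = self.config
        if T > c.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {c.max_len}")
        p = self.params
        x = ad.add(ad.gather(p["tok_emb"], ids), ad.gather(p["pos_emb"], np.arange(T)))
        # additive bias: padding keys are pushed to -inf before softmax
        attn_bias = (1.0 - mask)[:, None, None, :] * NEG_INF
        H, dh = c.n_heads, c.d_model // c.n_heads
        scale = 1.0 / np.sqrt(dh)
        for i in range(c.n_layers):
            pre = f"layer{i}."
            h = ad.layer_norm(x, p[pre + "ln1_g"], p[pre + "ln1_b"], c.ln_eps)

            def heads(name):
                y = ad.add(ad.matmul(h, p[pre + name]), p[pre + name + "_b"])
                y = ad.reshape(y, (B, T, H, dh))
                return ad.transpose(y, (0, 2, 1, 3))  # [B, H, T, dh]

            q, k, v = heads("wq"), heads("wk"), heads("wv")
            scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), scale)
            attn = ad.softmax(scores, bias=attn_bias)
            ctx = ad.matmul(attn, v)
            ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (B, T, c.d_model))
            x = ad.add(x, ad.add(ad.matmul(ctx, p[pre + "wo"]), p[pre + "wo_b"]))

            h2 = ad.layer_norm(x, p[pre + "ln2_g"], p[pre + "ln2_b"], c.ln_eps)
            ff = ad.gelu(ad.add(ad.matmul(h2, p[pre + "ff1"]), p[pre + "ff1_b"]))
            ff = ad.add(ad.matmul(ff, p[pre + "ff2"]), p[pre + "ff2_b"])
            x = ad.add(x, ff)
        return ad.layer_norm(x, p["lnf_g"], p["lnf_b"], c.ln_eps)

    def encode(self, ids: np.ndarray, attention_mask: np.ndarray) -> np.ndarray:
        """Inference-only forward pass returning a plain array."""
        return self.forward(ids, attention_mask).data

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.state_dict())
        (directory / "config.json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, directory: str | Path) -> "TransformerEncoder":
        directory = Path(directory)
        config = EncoderConfig(**json.loads((directory / "config.json").read_text()))
        enc = cls(config, seed=0)
        with np.load(directory / "weights.npz") as z:
            enc.load_state_dict({k: z[k] for k in z.files})
        return enc


class MLMHead:
    """Linear projection from hidden states to vocabulary logits."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w = Tensor(rng.normal(0.0, config.init_std, (config.d_model, config.vocab_size)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(config.vocab_size), requires_grad=True)

    @property
    def params(self) -> dict[str, Tensor]:
        return {"mlm.w": self.w, "mlm.b": self.b}

    def logits_at(self, hidden: Tensor, flat_positions: np.ndarray) -> Tensor:
        """Score only the selected (masked) positions — hidden is [B,T,d],
        ``flat_positions`` indexes into the flattened [B*T] axis."""
        B, T, d = hidden.data.shape
        flat = ad.reshape(hidden, (B * T, d))
        sel = ad.take_rows(flat, flat_positions)
        return ad.add(ad.matmul(sel, self.w), self.b)
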