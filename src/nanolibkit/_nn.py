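"""Numpy decoder-only transformer with optional low-rank adapters.

A deliberately small LLaMA-style decoder: pre-RMSNorm, multi-head causal
self-attention, SwiGLU feed-forward, learned absolute position
embeddings. Forward and backward passes are written out by hand so the
freeze semantics are explicit: every weight matrix can carry a low-rank
adapter pair (A, B) computing ``y = x W + s (x A) B``, and in adapter
mode gradients flow only into A and B while the base matrices stay
bitwise untouched.

All arrays are float32. Every projection that the adapter scheme targets
(wq, wk, wv, wo, wgate, wup, wdown) is a plain ``(d_in, d_out)`` matrix
applied on the right.
"""

from __future__ import annotations

import hashlib
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

ADAPTER_TARGETS = ("wq", "wk", "wv", "wo", "wgate", "wup", "wdown")

_EPS = 1e-6


def _rmsnorm_fwd(x: np.ndarray, g: np.ndarray):
    r = np.sqrt(np.mean(x * x, axis=-1, keepdims=True) + _EPS)
    n = x / r
    return n * g, (n, r)


def _rmsnorm_bwd(dy: np.ndarray, g: np.ndarray, cache):
    n, r = cache
    dg = np.sum(dy * n, axis=tuple(range(dy.ndim - 1)))
    dn = dy * g
    dx = (dn - n * np.mean(dn * n, axis=-1, keepdims=True)) / r
    return dx.astype(np.float32), dg.astype(np.float32)


def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


def _softmax(x: np.ndarray) -> np.ndarray:
    m = np.max(x, axis=-1, keepdims=True)
    e = np.exp(x - m)
    return e / np.sum(e, axis=-1, keepdims=True)


class Decoder:
    """Parameter container plus forward/backward for the toy decoder.

    ``params`` holds the base weights; ``lora`` (when attached) maps
    ``"l{i}.{target}"`` to an ``(A, B)`` pair. ``trainable_mode`` is
    ``"full"`` (base weights update, used for pretraining the toy base)
    or ``"lora"`` (base frozen, only adapters update).
    """

    def __init__(
        self,
        vocab_size: int,
        d_model: int,
        n_layers: int,
        n_heads: int,
        d_ff: int,
        max_len: int,
        seed: int,
    ):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.vocab_size = vocab_size
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.d_ff = d_ff
        self.max_len = max_len
        rng = np.random.default_rng(seed)

        def w(*shape):
            return (rng.standard_normal(shape) * 0.02).astype(np.float32)

        p: Dict[str, np.ndarray] = {
            "emb": w(vocab_size, d_model),
            "pos": w(max_len, d_model),
            "lnf": np.ones(d_model, dtype=np.float32),
            "wout": w(d_model, vocab_size),
        }
        for i in range(n_layers):
            p[f"l{i}.ln1"] = np.ones(d_model, dtype=np.float32)
            p[f"l{i}.ln2"] = np.ones(d_model, dtype=np.float32)
            for t in ("wq", "wk", "wv", "wo"):
                p[f"l{i}.{t}"] = w(d_model, d_model)
            p[f"l{i}.wgate"] = w(d_model, d_ff)
            p[f"l{i}.wup"] = w(d_model, d_ff)
            p[f"l{i}.wdown"] = w(d_ff, d_model)
        self.params = p
        self.lora: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None
        self.lora_scale = 1.0
        self.trainable_mode = "full"

    # ------------------------------------------------------------------
    def matrix_shapes(self) -> Dict[str, Tuple[int, int]]:
        """Shapes of the adapter-targetable matrices, keyed by target name."""
        return {
            "wq": (self.d_model, self.d_model),
            "wk": (self.d_model, self.d_model),
            "wv": (self.d_model, self.d_model),
            "wo": (self.d_model, self.d_model),
            "wgate": (self.d_model, self.d_ff),
            "wup": (self.d_model, self.d_ff),
            "wdown": (self.d_ff, self.d_model),
        }

    def attach_lora(
        self, targets: Sequence[str], rank: int, scale: float, seed: int
    ) -> None:
        """Create (A, B) pairs: A gaussian, B zero, so the adapted model is
        function-identical to the base at step 0."""
        shapes = self.matrix_shapes()
        for t in targets:
            if t not in shapes:
                raise ValueError(f"unknown adapter target {t!r}")
            d_in, d_out = shapes[t]
            if rank >= min(d_in, d_out):
                raise ValueError(
                    f"rank {rank} not << min dimension {min(d_in, d_out)} of {t}"
                )
        rng = np.random.default_rng(seed)
        self.lora = {}
        for i in range(self.n_layers):
            for t in targets:
                d_in, d_out = shapes[t]
                A = (rng.standard_normal((d_in, rank)) * 0.02).astype(np.float32)
                B = np.zeros((rank, d_out), dtype=np.float32)
                self.lora[f"l{i}.{t}"] = (A, B)
        self.lora_scale = float(scale)
        self.trainable_mode = "lora"

    def base_checksum(self) -> str:
        """SHA-256 over all base weights in key order (freeze witness)."""
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    def n_base_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def n_lora_params(self) -> int:
        if not self.lora:
            return 0
        return sum(A.size + B.size for A, B in self.lora.values())

    # ------------------------------------------------------------------
    def _lin_fwd(self, name: str, x2: np.ndarray, cache: Dict):
        W = self.params[name]
        y = x2 @ W
        xa = None
        if self.lora is not None and name in self.lora:
            A, B = self.lora[name]
            xa = x2 @ A
            y = y + self.lora_scale * (xa @ B)
        cache[name] = (x2, xa)
        return y

    def _lin_bwd(self, name: str, dy2: np.ndarray, cache: Dict, grads: Dict):
        x2, xa = cache[name]
        W = self.params[name]
        dx = dy2 @ W.T
        if self.lora is not None and name in self.lora:
            A, B = self.lora[name]
            dyB = dy2 @ B.T
            dx = dx + self.lora_scale * (dyB @ A.T)
            if self.trainable_mode == "lora":
                grads[f"{name}.A"] = grads.get(f"{name}.A", 0) + self.lora_scale * (
                    x2.T @ dyB
                )
                grads[f"{name}.B"] = grads.get(f"{name}.B", 0) + self.lora_scale * (
                    xa.T @ dy2
                )
        if self.trainable_mode == "full":
            grads[name] = grads.get(name, 0) + x2.T @ dy2
        return dx

    # ------------------------------------------------------------------
    def forward(self, tokens: np.ndarray):
        """Full-sequence forward. tokens: (B, T) int. Returns logits (B,T,V)
        and the cache needed for backward."""
        B, T = tokens.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.max_len}")
        H, dh = self.n_heads, self.d_head
        x = (self.params["emb"][tokens] + self.params["pos"][:T]).astype(np.float32)
        mask = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)
        caches: List[Dict] = []
        for i in range(self.n_layers):
            c: Dict = {"x0": x}
            h, c["ln1"] = _rmsnorm_fwd(x, self.params[f"l{i}.ln1"])
            h2d = h.reshape(B * T, -1)
            q = self._lin_fwd(f"l{i}.wq", h2d, c).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            k = self._lin_fwd(f"l{i}.wk", h2d, c).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            v = self._lin_fwd(f"l{i}.wv", h2d, c).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(dh) + mask
            probs = _softmax(scores)
            ctx = (probs @ v).transpose(0, 2, 1, 3).reshape(B * T, -1)
            c.update(q=q, k=k, v=v, probs=probs)
            o = self._lin_fwd(f"l{i}.wo", ctx, c).reshape(B, T, -1)
            x1 = x + o
            c["x1"] = x1
            hh, c["ln2"] = _rmsnorm_fwd(x1, self.params[f"l{i}.ln2"])
            hh2d = hh.reshape(B * T, -1)
            gpre = self._lin_fwd(f"l{i}.wgate", hh2d, c)
            upre = self._lin_fwd(f"l{i}.wup", hh2d, c)
            act = _silu(gpre) * upre
            c.update(gpre=gpre, upre=upre)
            dwn = self._lin_fwd(f"l{i}.wdown", act, c).reshape(B, T, -1)
            x = x1 + dwn
            caches.append(c)
        hf, lnf_cache = _rmsnorm_fwd(x, self.params["lnf"])
        logits = hf.reshape(B * T, -1) @ self.params["wout"]
        top = {"tokens": tokens, "hf": hf, "lnf": lnf_cache, "x_last": x}
        return logits.reshape(B, T, -1), (caches, top)

    def backward(self, dlogits: np.ndarray, cache) -> Dict[str, np.ndarray]:
        caches, top = cache
        tokens = top["tokens"]
        B, T = tokens.shape
        H, dh = self.n_heads, self.d_head
        grads: Dict[str, np.ndarray] = {}
        dl2 = dlogits.reshape(B * T, -1).astype(np.float32)
        if self.trainable_mode == "full":
            grads["wout"] = top["hf"].reshape(B * T, -1).T @ dl2
        dhf = (dl2 @ self.params["wout"].T).reshape(B, T, -1)
        dx, dgf = _rmsnorm_bwd(dhf, self.params["lnf"], top["lnf"])
        if self.trainable_mode == "full":
            grads["lnf"] = dgf
        for i in reversed(range(self.n_layers)):
            c = caches[i]
            # feed-forward branch
            dact = self._lin_bwd(f"l{i}.wdown", dx.reshape(B * T, -1), c, grads)
            sg = _silu(c["gpre"])
            dgpre = dact * c["upre"] * _silu_grad(c["gpre"])
            dupre = dact * sg
            dhh = self._lin_bwd(f"l{i}.wgate", dgpre, c, grads)
            dhh += self._lin_bwd(f"l{i}.wup", dupre, c, grads)
            dx1_ln, dg2 = _rmsnorm_bwd(
                dhh.reshape(B, T, -1), self.params[f"l{i}.ln2"], c["ln2"]
            )
            if self.trainable_mode == "full":
                grads[f"l{i}.ln2"] = dg2
            dx1 = dx + dx1_ln
            # attention branch
            dctx = self._lin_bwd(f"l{i}.wo", dx1.reshape(B * T, -1), c, grads)
            dctx = dctx.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            probs, q, k, v = c["probs"], c["q"], c["k"], c["v"]
            dprobs = dctx @ v.transpose(0, 1, 3, 2)
            dv = probs.transpose(0, 1, 3, 2) @ dctx
            dscores = probs * (dprobs - np.sum(dprobs * probs, axis=-1, keepdims=True))
            dscores /= np.sqrt(dh)
            dq = dscores @ k
            dk = dscores.transpose(0, 1, 3, 2) @ q
            def _merge(a):
                return a.transpose(0, 2, 1, 3).reshape(B * T, -1)
            dh_ = self._lin_bwd(f"l{i}.wq", _merge(dq), c, grads)
            dh_ += self._lin_bwd(f"l{i}.wk", _merge(dk), c, grads)
            dh_ += self._lin_bwd(f"l{i}.wv", _merge(dv), c, grads)
            dx0_ln, dg1 = _rmsnorm_bwd(
                dh_.reshape(B, T, -1), self.params[f"l{i}.ln1"], c["ln1"]
            )
            if self.trainable_mode == "full":
                grads[f"l{i}.ln1"] = dg1
            dx = dx1 + dx0_ln
        if self.trainable_mode == "full":
            demb = np.zeros_like(self.params["emb"])
            np.add.at(demb, tokens.ravel(), dx.reshape(B * T, -1))
            grads["emb"] = demb
            dpos = dx.sum(axis=0)
            gp = np.zeros_like(self.params["pos"])
            gp[:T] = dpos
            grads["pos"] = gp
        return grads

    # ------------------------------------------------------------------
    def step_forward(self, tokens_step: np.ndarray, pos: int, kv):
        """Incremental decode: one new token per batch row.

        ``kv`` is a per-layer list of (K, V) arrays of shape
        (B, H, t, dh), extended in place. Returns logits (B, V).
        """
        B = tokens_step.shape[0]
        H, dh = self.n_heads, self.d_head
        x = (self.params["emb"][tokens_step] + self.params["pos"][pos]).astype(
            np.float32
        )[:, None, :]
        cache: Dict = {}
        for i in range(self.n_layers):
            h, _ = _rmsnorm_fwd(x, self.params[f"l{i}.ln1"])
            h2 = h.reshape(B, -1)
            q = self._lin_fwd(f"l{i}.wq", h2, cache).reshape(B, H, 1, dh)
            k = self._lin_fwd(f"l{i}.wk", h2, cache).reshape(B, H, 1, dh)
            v = self._lin_fwd(f"l{i}.wv", h2, cache).reshape(B, H, 1, dh)
            if kv[i] is None:
                K, V = k, v
            else:
                K = np.concatenate([kv[i][0], k], axis=2)
                V = np.concatenate([kv[i][1], v], axis=2)
            kv[i] = (K, V)
            scores = (q @ K.transpose(0, 1, 3, 2)) / np.sqrt(dh)
            probs = _softmax(scores)
            ctx = (probs @ V).reshape(B, -1)
            o = self._lin_fwd(f"l{i}.wo", ctx, cache).reshape(B, 1, -1)
            x1 = x + o
            hh, _ = _rmsnorm_fwd(x1, self.params[f"l{i}.ln2"])
            hh2 = hh.reshape(B, -1)
            act = _silu(self._lin_fwd(f"l{i}.wgate", hh2, cache)) * self._lin_fwd(
                f"l{i}.wup", hh2, cache
            )
            x = x1 + self._lin_fwd(f"l{i}.wdown", act, cache).reshape(B, 1, -1)
        hf, _ = _rmsnorm_fwd(x, self.params["lnf"])
        return hf.reshape(B, -1) @ self.params["wout"]


def cross_entropy(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray):
    """Mean masked next-token cross-entropy and its gradient w.r.t. logits.

    logits: (B, T, V); targets/mask: (B, T). Positions with mask 0 are
    ignored.
    """
    B, T, V = logits.shape
    probs = _softmax(logits)
    n = max(int(mask.sum()), 1)
    tp = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
    loss = float(-(np.log(np.clip(tp, 1e-12, None)) * mask).sum() / n)
    dlogits = probs
    bidx = np.arange(B)[:, None], np.arange(T)[None, :]
    onehot_sub = np.zeros_like(probs)
    onehot_sub[bidx[0], bidx[1], targets] = 1.0
    dlogits = (dlogits - onehot_sub) * mask[..., None] / n
    return loss, dlogits.astype(np.float32)


class Adam:
    """Adam over a named parameter view (base weights or adapter pairs)."""

    def __init__(self, lr: float = 1e-3, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, tensors: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(tensors[k])
                self.v[k] = np.zeros_like(tensors[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            tensors[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                tensors[k].dtype
            )
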