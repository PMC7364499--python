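"""Multihead scaled dot-product self-attention over the Bi-LSTM output.

Each head projects the encoded sequence into a d/h-dimensional subspace,
attends with ``softmax(QKᵀ/√d_head)·V``, and the concatenated head outputs
are linearly mixed by an output matrix W (d × d). A pooling reduction (max
over time by default, mean available) yields the fixed-size sentence
representation consumed by the classifier.

The softmax scale is ``√(d/h)`` per head by default; ``scale_mode="model"``
switches to ``√d``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import EncodedSequence
from .errors import ValidationError

POOL_MODES = ("max", "mean")


@dataclass
class MultiheadParams:
    """Per-head projections stored as block-column matrices.

    ``Wq``/``Wk``/``Wv`` are (d, d); columns ``[i*dh:(i+1)*dh]`` belong to
    head i. ``Wo`` is the (d, d) output mix.
    """

    d: int
    heads: int
    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    Wo: np.ndarray
    scale_mode: str = "per_head"  # "per_head" -> sqrt(d/h), "model" -> sqrt(d)

    def __post_init__(self):
        if self.d % self.heads:
            raise ValidationError(
                f"model dim {self.d} not divisible by {self.heads} heads"
            )

    @property
    def head_dim(self) -> int:
        return self.d // self.heads

    @property
    def scale(self) -> float:
        return float(np.sqrt(self.d if self.scale_mode == "model" else self.head_dim))


def init_multihead(
    d: int,
    heads: int = 4,
    rng: np.random.Generator | None = None,
    scale_mode: str = "per_head",
) -> MultiheadParams:
    rng = rng or np.random.default_rng(0)
    s = 1.0 / np.sqrt(d)
    return MultiheadParams(
        d=d,
        heads=heads,
        Wq=rng.uniform(-s, s, (d, d)),
        Wk=rng.uniform(-s, s, (d, d)),
        Wv=rng.uniform(-s, s, (d, d)),
        Wo=rng.uniform(-s, s, (d, d)),
        scale_mode=scale_mode,
    )


def _masked_softmax(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise softmax over unmasked key columns."""
    neg = np.where(mask[None, :], 0.0, -np.inf)
    z = scores + neg
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def scaled_dot_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    mask: np.ndarray | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """``softmax(QKᵀ/scale) · V`` with zero weight on masked keys.

    ``scale`` defaults to √(key dim).
    """
    out, _ = _attention_forward(Q, K, V, mask, scale)
    return out


def _attention_forward(Q, K, V, mask, scale):
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[1] != K.shape[1] or K.shape[0] != V.shape[0]:
        raise ValidationError("attention dimension mismatch")
    if scale is None:
        scale = float(np.sqrt(K.shape[1]))
    if mask is None:
        mask = np.ones(K.shape[0], dtype=bool)
    S = (Q @ K.T) / scale
    P = _masked_softmax(S, mask)
    out = P @ V
    return out, dict(Q=Q, K=K, V=V, P=P, scale=scale)


def _attention_backward(dout, cache):
    Q, K, V, P, scale = cache["Q"], cache["K"], cache["V"], cache["P"], cache["scale"]
    dV = P.T @ dout
    dP = dout @ V.T
    # softmax rows: dS = P ⊙ (dP − rowsum(dP ⊙ P)); masked keys have P = 0
    dS = P * (dP - np.sum(dP * P, axis=1, keepdims=True))
    dQ = (dS @ K) / scale
    dK = (dS.T @ Q) / scale
    return dQ, dK, dV


def multihead(X: EncodedSequence | np.ndarray, params: MultiheadParams) -> np.ndarray:
    """Multihead self-attention; returns the mixed (n, d) output."""
    if isinstance(X, EncodedSequence):
        values, mask = X.values, X.mask
    else:
        values, mask = np.asarray(X, dtype=float), None
    Y, _ = _multihead_forward(values, mask, params)
    return Y


def _multihead_forward(values, mask, params: MultiheadParams):
    n, d = values.shape
    if d != params.d:
        raise ValidationError(f"input dim {d} != model dim {params.d}")
    if mask is None:
        mask = np.ones(n, dtype=bool)
    dh = params.head_dim
    Q = values @ params.Wq
    K = values @ params.Wk
    V = values @ params.Wv
    heads = []
    caches = []
    for i in range(params.heads):
        sl = slice(i * dh, (i + 1) * dh)
        out, c = _attention_forward(Q[:, sl], K[:, sl], V[:, sl], mask, params.scale)
        heads.append(out)
        caches.append(c)
    M = np.concatenate(heads, axis=1)
    Y = M @ params.Wo
    # masked rows produce no output
    Y = Y * mask[:, None]
    return Y, dict(values=values, mask=mask, M=M, caches=caches)


def _multihead_backward(dY, cache, params: MultiheadParams, grads, prefix="attn/"):
    values, mask, M = cache["values"], cache["mask"], cache["M"]
    dY = dY * mask[:, None]
    grads[f"{prefix}Wo"] += M.T @ dY
    dM = dY @ params.Wo.T
    dh = params.head_dim
    dQ = np.zeros_like(values @ params.Wq)
    dK = np.zeros_like(dQ)
    dV = np.zeros_like(dQ)
    for i, c in enumerate(cache["caches"]):
        sl = slice(i * dh, (i + 1) * dh)
        dq, dk, dv = _attention_backward(dM[:, sl], c)
        dQ[:, sl], dK[:, sl], dV[:, sl] = dq, dk, dv
    grads[f"{prefix}Wq"] += values.T @ dQ
    grads[f"{prefix}Wk"] += values.T @ dK
    grads[f"{prefix}Wv"] += values.T @ dV
    dX = dQ @ params.Wq.T + dK @ params.Wk.T + dV @ params.Wv.T
    return dX


@dataclass
class SentenceRepresentation:
    """Fixed-size sentence vector from pooling the attention output."""

    vector: np.ndarray
    mode: str


def pool(
    Y: np.ndarray, mask: np.ndarray | None = None, mode: str = "max"
) -> SentenceRepresentation:
    """Reduce (n, d) attention output to a single d-vector over unmasked rows."""
    B, _ = _pool_forward(Y, mask, mode)
    return SentenceRepresentation(vector=B, mode=mode)


def _pool_forward(Y, mask, mode):
    if mode not in POOL_MODES:
        raise ValidationError(f"unknown pooling mode {mode!r}")
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    mask = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("cannot pool a fully masked sequence")
    rows = np.flatnonzero(mask)
    if mode == "max":
        sub = Y[rows]
        arg = rows[np.argmax(sub, axis=0)]
        return Y[arg, np.arange(Y.shape[1])], dict(mode=mode, arg=arg, n=n)
    return Y[rows].mean(axis=0), dict(mode=mode, rows=rows, n=n)


def _pool_backward(dB, cache, d):
    dY = np.zeros((cache["n"], d))
    if cache["mode"] == "max":
        dY[cache["arg"], np.arange(d)] = dB
    else:
        dY[cache["rows"]] = dB / len(cache["rows"])
    return dY
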