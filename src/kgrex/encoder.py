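"""Token embedding and the bidirectional LSTM encoder.

Each token is represented by the concatenation of a word vector (dim 200 by
default) and three position-embedding lookups (dim 50 each), one per entity
role, indexed by the clipped signed distance to that entity's head token. The
sequence is then encoded by a Bi-LSTM (200 hidden units per direction by
default), forward and backward states concatenated per token.

Two LSTM cell variants are provided:

* ``paper_literal`` (default) — the gated unit with candidate
  ``g = tanh(W_xg x + W_hg (i ⊙ h_prev) + b_g)`` and highway-style state mix
  ``h = (1 − f) ⊙ h_prev + f ⊙ g``. In this cell the output gate and the
  memory cell ``c`` are computed but do not feed ``h``.
* ``standard`` — the textbook LSTM, ``h = o ⊙ tanh(c)``.

All layers carry hand-written analytic gradients, verified against finite
differences in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import ROLES, PositionFeatures, RelationInstance
from .errors import ValidationError

GATE_VARIANTS = ("paper_literal", "standard")

_GATES = ("i", "f", "o", "g")


def _sigmoid(x):
    # overflow-safe piecewise form
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# embedding tables


@dataclass
class EmbeddingTables:
    """Word table plus three position tables (drug / gene / mutation).

    Row 0 of the word table is the trainable OOV vector. Position tables have
    ``2 * max_distance + 1`` rows; a distance ``d`` maps to row
    ``d + max_distance``.
    """

    word_vocab: dict[str, int]  # word -> row (>= 1; row 0 is OOV)
    word: np.ndarray  # (V + 1, d_w)
    position: dict[str, np.ndarray]  # role -> (2 * max_distance + 1, d_p)
    max_distance: int
    train_words: bool = True

    @property
    def word_dim(self) -> int:
        return self.word.shape[1]

    @property
    def pos_dim(self) -> int:
        return self.position["drug"].shape[1]

    @property
    def row_dim(self) -> int:
        return self.word_dim + 3 * self.pos_dim

    def word_index(self, token: str) -> int:
        return self.word_vocab.get(token, 0)


def load_word_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """Read a text-format word-vector file.

    Both dialects are accepted and auto-detected: word2vec text (first line
    ``<count> <dim>``) and headerless GloVe.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        parts = first.split()
        if len(parts) != 2 or not all(p.lstrip("-").isdigit() for p in parts):
            # GloVe dialect: the first line is already a vector row
            if parts:
                vectors[parts[0]] = np.array(parts[1:], dtype=float)
        for line in fh:
            parts = line.split()
            if parts:
                vectors[parts[0]] = np.array(parts[1:], dtype=float)
    return vectors


def build_tables(
    vocabulary: list[str],
    word_dim: int = 200,
    pos_dim: int = 50,
    max_distance: int = 128,
    rng: np.random.Generator | None = None,
    word_vectors: dict[str, np.ndarray] | str | Path | None = None,
) -> EmbeddingTables:
    """Build embedding tables over a corpus vocabulary.

    Without pre-trained vectors, tables initialize uniformly in ±0.05. With a
    word-vector file (or dict), known words take their pre-trained rows and
    the rest — including the OOV row — stay at the random initialization.
    """
    rng = rng or np.random.default_rng(0)
    vocab = {w: i + 1 for i, w in enumerate(dict.fromkeys(vocabulary))}
    word = rng.uniform(-0.05, 0.05, (len(vocab) + 1, word_dim))
    if word_vectors is not None:
        if not isinstance(word_vectors, dict):
            word_vectors = load_word_vectors(word_vectors)
        for w, row in vocab.items():
            vec = word_vectors.get(w)
            if vec is not None:
                if vec.shape[0] != word_dim:
                    raise ValidationError(
                        f"word vector dim {vec.shape[0]} != table dim {word_dim}"
                    )
                word[row] = vec
    position = {
        role: rng.uniform(-0.05, 0.05, (2 * max_distance + 1, pos_dim))
        for role in ROLES
    }
    return EmbeddingTables(
        word_vocab=vocab, word=word, position=position, max_distance=max_distance
    )


def embed_sequence(
    instance: RelationInstance,
    features: PositionFeatures,
    tables: EmbeddingTables,
) -> np.ndarray:
    """Per-token rows ``[word; pos_drug; pos_gene; pos_mutation]``."""
    X, _ = _embed_forward(instance, features, tables)
    return X


def _embed_forward(instance, features, tables):
    n = len(instance.tokens)
    if any(len(features.distances[r]) != n for r in ROLES):
        raise ValidationError("position features not aligned with tokens")
    word_idx = np.array([tables.word_index(t) for t in instance.tokens])
    pos_idx = {
        role: features.distances[role] + tables.max_distance for role in ROLES
    }
    X = np.concatenate(
        [tables.word[word_idx]] + [tables.position[r][pos_idx[r]] for r in ROLES],
        axis=1,
    )
    return X, {"word_idx": word_idx, "pos_idx": pos_idx}


def _embed_backward(dX, cache, tables, grads):
    """Scatter sequence gradients back into the lookup tables."""
    d_w, d_p = tables.word_dim, tables.pos_dim
    if tables.train_words:
        np.add.at(grads["word"], cache["word_idx"], dX[:, :d_w])
    for j, role in enumerate(ROLES):
        sl = dX[:, d_w + j * d_p : d_w + (j + 1) * d_p]
        np.add.at(grads[f"pos_{role}"], cache["pos_idx"][role], sl)


# ---------------------------------------------------------------------------
# LSTM


@dataclass
class LSTMParams:
    """Gate weights of one LSTM direction.

    ``Wx``/``Wh`` map input and previous hidden state into each of the four
    pre-activations (input, forget, output, candidate); shapes (hidden,
    input_dim) and (hidden, hidden).
    """

    Wx: dict[str, np.ndarray]
    Wh: dict[str, np.ndarray]
    b: dict[str, np.ndarray]
    hidden: int
    variant: str = "paper_literal"

    def arrays(self, prefix: str) -> dict[str, np.ndarray]:
        out = {}
        for gate in _GATES:
            out[f"{prefix}Wx_{gate}"] = self.Wx[gate]
            out[f"{prefix}Wh_{gate}"] = self.Wh[gate]
            out[f"{prefix}b_{gate}"] = self.b[gate]
        return out


def init_lstm(
    input_dim: int,
    hidden: int,
    variant: str = "paper_literal",
    rng: np.random.Generator | None = None,
) -> LSTMParams:
    if variant not in GATE_VARIANTS:
        raise ValidationError(f"unknown gate variant {variant!r}")
    rng = rng or np.random.default_rng(0)
    sx = 1.0 / np.sqrt(input_dim)
    sh = 1.0 / np.sqrt(hidden)
    return LSTMParams(
        Wx={g: rng.uniform(-sx, sx, (hidden, input_dim)) for g in _GATES},
        Wh={g: rng.uniform(-sh, sh, (hidden, hidden)) for g in _GATES},
        b={g: np.zeros(hidden) for g in _GATES},
        hidden=hidden,
        variant=variant,
    )


def _cell_forward(x, h_prev, c_prev, params: LSTMParams):
    Wx, Wh, b = params.Wx, params.Wh, params.b
    if x.shape[-1] != Wx["i"].shape[1] or h_prev.shape[-1] != params.hidden:
        raise ValidationError("lstm_cell shape mismatch")
    i = _sigmoid(Wx["i"] @ x + Wh["i"] @ h_prev + b["i"])
    f = _sigmoid(Wx["f"] @ x + Wh["f"] @ h_prev + b["f"])
    o = _sigmoid(Wx["o"] @ x + Wh["o"] @ h_prev + b["o"])
    if params.variant == "paper_literal":
        g_in = i * h_prev
        g = np.tanh(Wx["g"] @ x + Wh["g"] @ g_in + b["g"])
        c = f * c_prev + i * g
        h = (1.0 - f) * h_prev + f * g
    else:
        g_in = h_prev
        g = np.tanh(Wx["g"] @ x + Wh["g"] @ g_in + b["g"])
        c = f * c_prev + i * g
        h = o * np.tanh(c)
    cache = dict(x=x, h_prev=h_prev, c_prev=c_prev, i=i, f=f, o=o, g=g,
                 g_in=g_in, c=c)
    return h, c, cache


def lstm_cell(x, h_prev, c_prev, params: LSTMParams):
    """One LSTM step; returns ``(h_t, c_t)``."""
    h, c, _ = _cell_forward(
        np.asarray(x, dtype=float),
        np.asarray(h_prev, dtype=float),
        np.asarray(c_prev, dtype=float),
        params,
    )
    return h, c


def _cell_backward(dh, dc, cache, params: LSTMParams, grads, prefix):
    """Backprop one step. Returns (dx, dh_prev, dc_prev); parameter grads are
    accumulated into ``grads`` under keys ``{prefix}Wx_i`` etc."""
    i, f, o, g = cache["i"], cache["f"], cache["o"], cache["g"]
    h_prev, c_prev, x = cache["h_prev"], cache["c_prev"], cache["x"]
    di = np.zeros_like(i)
    df = np.zeros_like(f)
    do = np.zeros_like(o)
    dg = np.zeros_like(g)
    dh_prev = np.zeros_like(h_prev)

    if params.variant == "paper_literal":
        dg += dh * f
        df += dh * (g - h_prev)
        dh_prev += dh * (1.0 - f)
    else:
        tc = np.tanh(cache["c"])
        do += dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
    # memory cell c = f*c_prev + i*g (disconnected from h in the literal cell)
    df += dc * c_prev
    di += dc * g
    dg += dc * i
    dc_prev = dc * f

    da_g = dg * (1.0 - g * g)
    dg_in = params.Wh["g"].T @ da_g
    if params.variant == "paper_literal":
        di += dg_in * h_prev
        dh_prev += dg_in * i
    else:
        dh_prev += dg_in

    da = {
        "i": di * i * (1.0 - i),
        "f": df * f * (1.0 - f),
        "o": do * o * (1.0 - o),
        "g": da_g,
    }
    dx = np.zeros_like(x)
    for gate in _GATES:
        inp = cache["g_in"] if gate == "g" else h_prev
        grads[f"{prefix}Wx_{gate}"] += np.outer(da[gate], x)
        grads[f"{prefix}Wh_{gate}"] += np.outer(da[gate], inp)
        grads[f"{prefix}b_{gate}"] += da[gate]
        dx += params.Wx[gate].T @ da[gate]
        if gate != "g":
            dh_prev += params.Wh[gate].T @ da[gate]
    return dx, dh_prev, dc_prev


@dataclass
class EncodedSequence:
    """Contextual token vectors (n, 2*hidden); masked rows are zero."""

    values: np.ndarray
    mask: np.ndarray

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def _direction_forward(X, params, reverse, rec_mask=None):
    n = X.shape[0]
    u = params.hidden
    h = np.zeros(u)
    c = np.zeros(u)
    H = np.zeros((n, u))
    caches = []
    order = range(n - 1, -1, -1) if reverse else range(n)
    for t in order:
        h_in = h if rec_mask is None else h * rec_mask
        h, c, cache = _cell_forward(X[t], h_in, c, params)
        cache["t"] = t
        caches.append(cache)
        H[t] = h
    return H, caches


def _direction_backward(dH, caches, params, grads, prefix, n_in, rec_mask=None):
    dX = np.zeros((n_in, params.Wx["i"].shape[1]))
    dh_next = np.zeros(params.hidden)
    dc_next = np.zeros(params.hidden)
    for cache in reversed(caches):
        t = cache["t"]
        dx, dh_prev, dc_prev = _cell_backward(
            dH[t] + dh_next, dc_next, cache, params, grads, prefix
        )
        if rec_mask is not None:
            dh_prev = dh_prev * rec_mask
        dX[t] += dx
        dh_next, dc_next = dh_prev, dc_prev
    return dX


def encode_bilstm(
    embedded: np.ndarray,
    mask: np.ndarray | None,
    params_fwd: LSTMParams,
    params_bwd: LSTMParams,
) -> EncodedSequence:
    """Concatenate forward and backward LSTM states per token.

    ``mask`` marks valid rows; padding must trail the valid region (right
    padding) and never influences valid outputs. Initial states are zero and
    the backward pass runs over the reversed valid region only.
    """
    H, _ = _bilstm_forward(embedded, mask, params_fwd, params_bwd)
    return H


def _bilstm_forward(embedded, mask, params_fwd, params_bwd,
                    rec_mask_fwd=None, rec_mask_bwd=None):
    embedded = np.asarray(embedded, dtype=float)
    if embedded.ndim != 2 or embedded.shape[0] == 0:
        raise ValidationError("encode_bilstm requires a non-empty 2-D input")
    n = embedded.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValidationError("empty sequence")
    if not mask[:n_valid].all():
        raise ValidationError("mask must be right-padded")
    Xv = embedded[:n_valid]
    Hf, cf = _direction_forward(Xv, params_fwd, reverse=False, rec_mask=rec_mask_fwd)
    Hb, cb = _direction_forward(Xv, params_bwd, reverse=True, rec_mask=rec_mask_bwd)
    out = np.zeros((n, params_fwd.hidden + params_bwd.hidden))
    out[:n_valid] = np.concatenate([Hf, Hb], axis=1)
    cache = dict(cf=cf, cb=cb, n_valid=n_valid, n=n,
                 rec_mask_fwd=rec_mask_fwd, rec_mask_bwd=rec_mask_bwd)
    return EncodedSequence(values=out, mask=mask), cache


def _bilstm_backward(dH, cache, params_fwd, params_bwd, grads):
    nv = cache["n_valid"]
    u = params_fwd.hidden
    dXf = _direction_backward(
        dH[:nv, :u], cache["cf"], params_fwd, grads, "lstm_fwd/", nv,
        rec_mask=cache["rec_mask_fwd"],
    )
    dXb = _direction_backward(
        dH[:nv, u:], cache["cb"], params_bwd, grads, "lstm_bwd/", nv,
        rec_mask=cache["rec_mask_bwd"],
    )
    dX = np.zeros((cache["n"], dXf.shape[1]))
    dX[:nv] = dXf + dXb
    return dX
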