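"""End-to-end relation classifier: embeddings → Bi-LSTM → multihead attention
→ pooling → concatenation with KG relation vectors → softmax.

The pooled sentence vector B is concatenated with two knowledge-graph side
channels, the entity-difference vectors gene − drug and mutation − drug, and
the result (400 + 50 + 50 = 500 dims at the defaults) is classified by a
softmax layer trained with cross-entropy. Training uses Adam (lr 0.001),
minibatches of 6, and keeps the parameter snapshot with the best validation
accuracy. A single master seed fans out to fold splitting, parameter
initialization and dropout.

Binary (drug–mutation) instances carry no drug–gene pair; that slot is
zero-filled, and the shipped default for binary mode is KG-off because
relation-typed KG vectors would leak the yes/no label directly.
"""
from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import attention as attn_mod
from . import encoder as enc_mod
from .attention import MultiheadParams, SentenceRepresentation, init_multihead
from .corpus import Dataset, LabelScheme, RelationInstance, compute_position_features, split_folds
from .encoder import EmbeddingTables, LSTMParams, build_tables, init_lstm
from .errors import ValidationError
from .kg import TranslationParams, relation_vector

logger = logging.getLogger("kgrex")

LENGTH_BUCKETS = ((0, 45), (45, 75), (75, None))


def _bucket_name(lo, hi):
    return f"{lo}-{hi if hi is not None else ''}"


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults mirror the reference design."""

    batch_size: int = 6
    learning_rate: float = 0.001
    epochs: int = 10
    heads: int = 4
    word_dim: int = 200
    pos_dim: int = 50
    hidden: int = 200
    kg_dim: int = 50
    max_distance: int = 128
    recurrent_dropout: float = 0.5
    output_dropout: float = 0.5
    kg_variant: str = "transR"
    pooling: str = "max"
    gate_variant: str = "paper_literal"
    attention_scale: str = "per_head"
    freeze_word_vectors: bool = False
    kg_for_binary: bool = False
    grad_clip: float = 5.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("batch_size", "epochs", "heads", "word_dim", "pos_dim",
                     "hidden", "kg_dim", "max_distance"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not (0 <= self.recurrent_dropout < 1 and 0 <= self.output_dropout < 1):
            raise ValidationError("dropout rates must be in [0, 1)")

    @property
    def model_dim(self) -> int:
        return 2 * self.hidden

    @classmethod
    def from_file(cls, path: str | Path) -> "TrainConfig":
        """Load a flat YAML/JSON key-value config; unknown keys are an error."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ClassifierParams:
    """Softmax layer: logits = W z + b with z = [B; R_dg; R_dm]."""

    W: np.ndarray  # (C, d + 2k)
    b: np.ndarray  # (C,)


def concat_features(
    B: SentenceRepresentation | np.ndarray,
    r_dg: np.ndarray | None,
    r_dm: np.ndarray | None,
    k: int,
) -> np.ndarray:
    """``[B; R_drug-gene; R_drug-mutation]``; absent slots become zeros(k)."""
    vec = B.vector if isinstance(B, SentenceRepresentation) else np.asarray(B)
    dg = np.zeros(k) if r_dg is None else np.asarray(r_dg, dtype=float)
    dm = np.zeros(k) if r_dm is None else np.asarray(r_dm, dtype=float)
    if dg.shape != (k,) or dm.shape != (k,):
        raise ValidationError("relation vector dimension mismatch")
    return np.concatenate([vec, dg, dm])


def predict(z: np.ndarray, params: ClassifierParams) -> np.ndarray:
    """Softmax class probabilities for one feature vector."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] != params.W.shape[1]:
        raise ValidationError("feature vector does not match classifier shape")
    logits = params.W @ z + params.b
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def cross_entropy(probabilities, gold) -> float:
    """Mean ``−log p(gold)`` over a batch (or a single distribution).

    Probabilities at the gold index are clamped at 1e−12; a clamp is logged.
    """
    probs = np.atleast_2d(np.asarray(probabilities, dtype=float))
    gold = np.atleast_1d(gold)
    p = probs[np.arange(len(gold)), gold]
    if (p < 1e-12).any():
        logger.warning("cross_entropy: clamped %d zero probabilities", int((p < 1e-12).sum()))
    return float(-np.log(np.maximum(p, 1e-12)).mean())


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Accuracy, macro-F1, confusion matrix (gold rows × predicted columns)
    and per-length-bucket accuracy."""

    accuracy: float
    macro_f1: float
    confusion: np.ndarray
    classes: tuple[str, ...]
    bucket_accuracy: dict[str, float | None] = field(default_factory=dict)
    bucket_counts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_confusion(cls, matrix, classes) -> "EvalReport":
        m = np.asarray(matrix, dtype=float)
        total = m.sum()
        acc = float(np.trace(m) / total)
        diag = np.diag(m)
        gold = m.sum(axis=1)
        pred = m.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            precision = np.where(pred > 0, diag / np.maximum(pred, 1), 0.0)
            recall = np.where(gold > 0, diag / np.maximum(gold, 1), 0.0)
            denom = precision + recall
            f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-12), 0.0)
        return cls(
            accuracy=acc,
            macro_f1=float(f1.mean()),
            confusion=m.astype(int),
            classes=tuple(classes),
        )

    @classmethod
    def from_predictions(cls, gold, pred, lengths, classes) -> "EvalReport":
        gold = np.asarray(gold)
        pred = np.asarray(pred)
        C = len(classes)
        m = np.zeros((C, C), dtype=int)
        np.add.at(m, (gold, pred), 1)
        rep = cls.from_confusion(m, classes)
        lengths = np.asarray(lengths)
        correct = gold == pred
        for lo, hi in LENGTH_BUCKETS:
            sel = (lengths >= lo) & ((lengths < hi) if hi is not None else True)
            name = _bucket_name(lo, hi)
            rep.bucket_counts[name] = int(sel.sum())
            rep.bucket_accuracy[name] = (
                float(correct[sel].mean()) if sel.any() else None
            )
        return rep

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "bucket_accuracy": self.bucket_accuracy,
            "bucket_counts": self.bucket_counts,
        }


# ---------------------------------------------------------------------------
# the model bundle


class RelationModel:
    """Trained parameter bundle with forward/backward passes."""

    def __init__(
        self,
        tables: EmbeddingTables,
        lstm_fwd: LSTMParams,
        lstm_bwd: LSTMParams,
        attn: MultiheadParams,
        clf: ClassifierParams,
        scheme: LabelScheme,
        config: TrainConfig,
        kg_params: TranslationParams | None = None,
    ):
        self.tables = tables
        self.lstm_fwd = lstm_fwd
        self.lstm_bwd = lstm_bwd
        self.attn = attn
        self.clf = clf
        self.scheme = scheme
        self.config = config
        self.kg_params = kg_params

    # -- parameter registry -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        params = {
            "word": self.tables.word,
            **{f"pos_{r}": self.tables.position[r] for r in ("drug", "gene", "mutation")},
            **self.lstm_fwd.arrays("lstm_fwd/"),
            **self.lstm_bwd.arrays("lstm_bwd/"),
            "attn/Wq": self.attn.Wq,
            "attn/Wk": self.attn.Wk,
            "attn/Wv": self.attn.Wv,
            "attn/Wo": self.attn.Wo,
            "clf/W": self.clf.W,
            "clf/b": self.clf.b,
        }
        if self.config.freeze_word_vectors:
            params.pop("word")
        return params

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.parameters().items()}

    # -- KG side information -------------------------------------------------

    @property
    def use_kg(self) -> bool:
        if self.kg_params is None:
            return False
        if self.scheme.mode == "binary" and not self.config.kg_for_binary:
            return False
        return True

    @property
    def kg_dim(self) -> int:
        return self.kg_params.k if self.kg_params is not None else self.config.kg_dim

    def kg_vectors(self, instance: RelationInstance):
        k = self.kg_dim
        if not self.use_kg:
            return np.zeros(k), np.zeros(k)
        drug = instance.mentions.get("drug")
        gene = instance.mentions.get("gene")
        mut = instance.mentions.get("mutation")
        r_dg = (
            relation_vector(self.kg_params, drug.entity_id, gene.entity_id)
            if drug and gene
            else np.zeros(k)
        )
        r_dm = (
            relation_vector(self.kg_params, drug.entity_id, mut.entity_id)
            if drug and mut
            else np.zeros(k)
        )
        return r_dg, r_dm

    # -- forward / backward ---------------------------------------------------

    def _forward(self, instance: RelationInstance, train: bool = False,
                 rng: np.random.Generator | None = None):
        cfg = self.config
        feats = compute_position_features(instance, cfg.max_distance)
        X, ecache = enc_mod._embed_forward(instance, feats, self.tables)

        rec_f = rec_b = None
        out_mask = None
        if train:
            keep_r = 1.0 - cfg.recurrent_dropout
            keep_o = 1.0 - cfg.output_dropout
            if keep_r < 1.0:
                rec_f = (rng.random(cfg.hidden) < keep_r) / keep_r
                rec_b = (rng.random(cfg.hidden) < keep_r) / keep_r
            if keep_o < 1.0:
                out_mask = (rng.random(cfg.model_dim) < keep_o) / keep_o

        enc, bcache = enc_mod._bilstm_forward(
            X, None, self.lstm_fwd, self.lstm_bwd, rec_f, rec_b
        )
        Y, acache = attn_mod._multihead_forward(enc.values, enc.mask, self.attn)
        B, pcache = attn_mod._pool_forward(Y, enc.mask, cfg.pooling)
        B_used = B if out_mask is None else B * out_mask
        r_dg, r_dm = self.kg_vectors(instance)
        z = np.concatenate([B_used, r_dg, r_dm])
        probs = predict(z, self.clf)
        cache = dict(ecache=ecache, bcache=bcache, acache=acache, pcache=pcache,
                     z=z, out_mask=out_mask, probs=probs)
        return probs, cache

    def _backward(self, instance, cache, gold_idx, grads, weight=1.0):
        cfg = self.config
        dlogits = cache["probs"].copy()
        dlogits[gold_idx] -= 1.0
        dlogits *= weight
        grads["clf/W"] += np.outer(dlogits, cache["z"])
        grads["clf/b"] += dlogits
        dz = self.clf.W.T @ dlogits
        dB = dz[: cfg.model_dim]
        if cache["out_mask"] is not None:
            dB = dB * cache["out_mask"]
        dY = attn_mod._pool_backward(dB, cache["pcache"], cfg.model_dim)
        dH = attn_mod._multihead_backward(dY, cache["acache"], self.attn, grads)
        dX = enc_mod._bilstm_backward(
            dH, cache["bcache"], self.lstm_fwd, self.lstm_bwd, grads
        )
        enc_mod._embed_backward(dX, cache["ecache"], self.tables, grads)

    # -- inference ------------------------------------------------------------

    def predict_proba(self, instance: RelationInstance) -> np.ndarray:
        probs, _ = self._forward(instance, train=False)
        return probs

    def predict_label(self, instance: RelationInstance) -> str:
        probs = self.predict_proba(instance)
        return self.scheme.classes[int(np.argmax(probs))]  # ties -> lowest index

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for k, v in self.parameters().items():
            v[...] = snap[k]


def build_model(
    scheme: LabelScheme,
    tables: EmbeddingTables,
    config: TrainConfig,
    kg_params: TranslationParams | None = None,
    rng: np.random.Generator | None = None,
) -> RelationModel:
    rng = rng or np.random.default_rng(0)
    d = config.model_dim
    k = kg_params.k if kg_params is not None else config.kg_dim
    lstm_fwd = init_lstm(tables.row_dim, config.hidden, config.gate_variant, rng)
    lstm_bwd = init_lstm(tables.row_dim, config.hidden, config.gate_variant, rng)
    attn = init_multihead(d, config.heads, rng, config.attention_scale)
    C = len(scheme.classes)
    s = 1.0 / np.sqrt(d + 2 * k)
    clf = ClassifierParams(W=rng.uniform(-s, s, (C, d + 2 * k)), b=np.zeros(C))
    tables.train_words = not config.freeze_word_vectors
    return RelationModel(tables, lstm_fwd, lstm_bwd, attn, clf, scheme, config, kg_params)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps=1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def train_model(
    train: Dataset,
    val: Dataset | None,
    kg_params: TranslationParams | None,
    tables: EmbeddingTables | None,
    config: TrainConfig,
) -> RelationModel:
    """Train the full classifier end to end.

    After each epoch the model is scored on the validation set and the
    best-validation-accuracy snapshot is returned; with an empty validation
    set the final epoch wins. Deterministic given ``config.rng_seed``.
    """
    if len(train) == 0:
        raise ValidationError("empty training set")
    ss = np.random.SeedSequence(config.rng_seed)
    s_init, s_drop, s_shuffle = [np.random.default_rng(c) for c in ss.spawn(3)]
    if tables is None:
        tables = build_tables(
            train.vocabulary(), config.word_dim, config.pos_dim,
            config.max_distance, s_init,
        )
    model = build_model(train.scheme, tables, config, kg_params, s_init)
    params = model.parameters()
    opt = _Adam(params, config.learning_rate)
    best_acc, best_snap = -1.0, None
    n = len(train)
    for epoch in range(1, config.epochs + 1):
        order = s_shuffle.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            grads = model.zero_grads()
            batch_loss = 0.0
            for i in idx:
                inst = train.instances[i]
                gold = train.scheme.index(inst.label)
                probs, cache = model._forward(inst, train=True, rng=s_drop)
                batch_loss += cross_entropy(probs, gold)
                model._backward(inst, cache, gold, grads, weight=1.0 / len(idx))
            _clip_grads(grads, config.grad_clip)
            opt.step(params, grads)
            epoch_loss += batch_loss / len(idx) * len(idx) / n
        msg = f"epoch {epoch}: train_loss={epoch_loss:.4f}"
        if val is not None and len(val) > 0:
            rep = evaluate(model, val)
            msg += f" val_acc={rep.accuracy:.4f}"
            if rep.accuracy > best_acc:
                best_acc, best_snap = rep.accuracy, model.snapshot()
        logger.info(msg)
    if best_snap is not None:
        model.restore(best_snap)
    return model


def evaluate(model: RelationModel, test: Dataset) -> EvalReport:
    """Argmax predictions (ties to the lowest class index) with accuracy,
    macro-F1, confusion matrix and per-length-bucket accuracy."""
    if len(test) == 0:
        raise ValidationError("empty test set")
    if test.scheme != model.scheme:
        raise ValidationError("label scheme mismatch between model and data")
    gold, pred, lengths = [], [], []
    for inst in test.instances:
        probs = model.predict_proba(inst)
        gold.append(test.scheme.index(inst.label))
        pred.append(int(np.argmax(probs)))
        lengths.append(len(inst.tokens))
    return EvalReport.from_predictions(gold, pred, lengths, test.scheme.classes)


def cross_validate(
    dataset: Dataset,
    kg_params: TranslationParams | None,
    tables: EmbeddingTables | None,
    config: TrainConfig,
    k: int = 5,
    validation_size: int = 200,
) -> dict:
    """k-fold cross-validation; mean test accuracy is the arithmetic mean of
    the per-fold accuracies."""
    folds = split_folds(len(dataset), k, validation_size, config.rng_seed)
    reports = []
    for f, (tr, va, te) in enumerate(folds):
        logger.info("fold %d: train=%d val=%d test=%d", f, len(tr), len(va), len(te))
        model = train_model(
            dataset.subset(tr), dataset.subset(va), kg_params, copy.deepcopy(tables), config
        )
        reports.append(evaluate(model, dataset.subset(te)))
    return {
        "mean_accuracy": float(np.mean([r.accuracy for r in reports])),
        "reports": reports,
    }


def save_model(model: RelationModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {k.replace("/", "__"): v for k, v in model.parameters().items()}
    arrays["word"] = model.tables.word  # present even when frozen
    np.savez(out / "model.npz", **arrays)
    manifest = {
        "config": asdict(model.config),
        "scheme": {"mode": model.scheme.mode, "classes": list(model.scheme.classes)},
        "word_vocab": model.tables.word_vocab,
    }
    (out / "model.json").write_text(json.dumps(manifest))


def load_model(in_dir: str | Path, kg_params: TranslationParams | None = None) -> RelationModel:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "model.json").read_text())
    config = TrainConfig(**manifest["config"])
    scheme = LabelScheme(manifest["scheme"]["mode"], tuple(manifest["scheme"]["classes"]))
    arrays = np.load(in_dir / "model.npz")
    rng = np.random.default_rng(0)
    tables = EmbeddingTables(
        word_vocab=manifest["word_vocab"],
        word=arrays["word"],
        position={r: arrays[f"pos_{r}"] for r in ("drug", "gene", "mutation")},
        max_distance=config.max_distance,
        train_words=not config.freeze_word_vectors,
    )
    model = build_model(scheme, tables, config, kg_params, rng)
    for key, value in model.parameters().items():
        value[...] = arrays[key.replace("/", "__")]
    return model
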