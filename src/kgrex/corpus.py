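"""Data model and I/O for cross-sentence n-ary relation instances.

A relation instance is a short multi-sentence passage in which a drug, a gene
and a mutation are each mentioned once (drug and mutation only for binary
instances), annotated with the interaction type that the passage expresses.
Instances are stored as JSON-lines with sentence-local token coordinates and
flattened to a single token sequence in memory.

Position features follow the relative-distance convention of position-embedding
relation extractors: for every token the signed distance to each entity
mention's head token, ``d = token_index - head_index``, so a token to the right
of an entity gets a positive distance.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, ValidationError

ROLES = ("drug", "gene", "mutation")
MULTICLASS_LABELS = (
    "resistance or nonresponse",
    "sensitivity",
    "response",
    "resistance",
    "none",
)
BINARY_LABELS = ("yes", "no")

# characters stripped from token edges; tokens that are nothing but these vanish
_PUNCT = ".,;:!?()\"'“”"


@dataclass(frozen=True)
class LabelScheme:
    """Label inventory: five interaction types, or their yes/no collapse."""

    mode: str  # "binary" | "multiclass"
    classes: tuple[str, ...]

    @classmethod
    def multiclass(cls) -> "LabelScheme":
        return cls("multiclass", MULTICLASS_LABELS)

    @classmethod
    def binary(cls) -> "LabelScheme":
        return cls("binary", BINARY_LABELS)

    @property
    def required_roles(self) -> tuple[str, ...]:
        return ("drug", "mutation") if self.mode == "binary" else ROLES

    def map_label(self, raw: str) -> str:
        """Map a raw label into this scheme.

        Binary mode collapses every positive fine-grained label to "yes" and
        "none" to "no"; labels already in the scheme pass through.
        """
        if raw in self.classes:
            return raw
        if self.mode == "binary" and raw in MULTICLASS_LABELS:
            return "no" if raw == "none" else "yes"
        raise ValidationError(f"unknown label {raw!r} for scheme {self.mode}")

    def index(self, label: str) -> int:
        return self.classes.index(label)


@dataclass(frozen=True)
class Mention:
    role: str
    entity_id: str
    span: tuple[int, int]  # 0-based, half-open, in flat token coordinates

    @property
    def head(self) -> int:
        """Anchor token of the mention: its first token."""
        return self.span[0]


@dataclass
class RelationInstance:
    doc_id: str
    tokens: list[str]
    sentence_breaks: list[int]  # start index of every sentence, first is 0
    mentions: dict[str, Mention]  # keyed by role
    label: str

    def validate(self, scheme: LabelScheme) -> None:
        n = len(self.tokens)
        for role in scheme.required_roles:
            if role not in self.mentions:
                raise ValidationError(
                    f"{self.doc_id}: missing mention for role {role!r}"
                )
        for m in self.mentions.values():
            if m.role not in ROLES:
                raise ValidationError(f"{self.doc_id}: unknown role {m.role!r}")
            s, e = m.span
            if not (0 <= s < e <= n):
                raise ValidationError(
                    f"{self.doc_id}: span {m.span} out of range for {n} tokens"
                )
        if self.label not in scheme.classes:
            raise ValidationError(f"{self.doc_id}: unknown label {self.label!r}")
        if not self.sentence_breaks or self.sentence_breaks[0] != 0:
            raise ValidationError(f"{self.doc_id}: sentence_breaks must start at 0")

    def sentences(self) -> list[list[str]]:
        """Recover sentence-local token lists from the flat sequence."""
        bounds = list(self.sentence_breaks) + [len(self.tokens)]
        return [self.tokens[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class PositionFeatures:
    """Per-token signed distances to each entity head, clipped to ±max_distance."""

    distances: dict[str, np.ndarray]
    max_distance: int


@dataclass
class Dataset:
    instances: list[RelationInstance]
    scheme: LabelScheme

    def __len__(self) -> int:
        return len(self.instances)

    def subset(self, indices: Iterable[int]) -> "Dataset":
        return Dataset([self.instances[i] for i in indices], self.scheme)

    def labels(self) -> np.ndarray:
        return np.array([self.scheme.index(i.label) for i in self.instances])

    def cross_sentence_share(self) -> float:
        """Percentage of instances spanning more than one sentence."""
        n_cross = sum(1 for i in self.instances if len(i.sentence_breaks) > 1)
        return cross_sentence_share(len(self) - n_cross, n_cross)

    def vocabulary(self) -> list[str]:
        seen: dict[str, None] = {}
        for inst in self.instances:
            for tok in inst.tokens:
                seen.setdefault(tok)
        return list(seen)


def cross_sentence_share(n_single: int, n_cross: int) -> float:
    """Cross-sentence percentage, ``100 * cross / (single + cross)``."""
    total = n_single + n_cross
    if total <= 0:
        raise ValidationError("counts must be positive")
    return 100.0 * n_cross / total


def normalize_tokens(raw_sentences: Sequence[str]) -> list[list[str]]:
    """Whitespace tokenization with edge punctuation stripped.

    Standalone punctuation marks disappear entirely; interior punctuation
    (hyphens, decimal points) is preserved. Idempotent on its own output.
    """
    out = []
    for sent in raw_sentences:
        toks = []
        for raw in sent.split():
            tok = raw.strip(_PUNCT)
            if tok:
                toks.append(tok)
        out.append(toks)
    return out


def _flatten(sentences: list[list[str]]):
    tokens: list[str] = []
    breaks: list[int] = []
    for sent in sentences:
        breaks.append(len(tokens))
        tokens.extend(sent)
    return tokens, breaks


def read_instances(path: str | Path, scheme: LabelScheme) -> Dataset:
    """Read a JSON-lines instance file.

    Each line holds ``doc_id``, ``sentences`` (list of token lists),
    ``mentions`` (role, entity_id, sentence_index, token_start, token_end)
    and ``label``. Spans are re-indexed to the flattened token sequence and
    labels are remapped into the requested scheme.
    """
    instances = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: malformed JSON on line {lineno}: {exc}")
            try:
                sentences = rec["sentences"]
                tokens, breaks = _flatten(sentences)
                mentions = {}
                for m in rec["mentions"]:
                    role = m["role"]
                    if role not in ROLES:
                        raise ValidationError(
                            f"line {lineno}: unknown role {role!r}"
                        )
                    off = breaks[m["sentence_index"]]
                    mentions[role] = Mention(
                        role=role,
                        entity_id=m["entity_id"],
                        span=(off + m["token_start"], off + m["token_end"]),
                    )
                inst = RelationInstance(
                    doc_id=rec["doc_id"],
                    tokens=tokens,
                    sentence_breaks=breaks,
                    mentions=mentions,
                    label=scheme.map_label(rec["label"]),
                )
            except (KeyError, IndexError, TypeError) as exc:
                raise ParseError(f"{path}: bad record on line {lineno}: {exc!r}")
            inst.validate(scheme)
            instances.append(inst)
    if not instances:
        raise ValidationError(f"{path}: empty dataset")
    return Dataset(instances, scheme)


def write_instances(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset back to JSON-lines, restoring sentence-local spans."""
    with open(path, "w", encoding="utf-8") as fh:
        for inst in dataset.instances:
            bounds = list(inst.sentence_breaks) + [len(inst.tokens)]
            mentions = []
            for m in inst.mentions.values():
                s_idx = max(
                    i for i, b in enumerate(inst.sentence_breaks) if b <= m.span[0]
                )
                off = inst.sentence_breaks[s_idx]
                mentions.append(
                    {
                        "role": m.role,
                        "entity_id": m.entity_id,
                        "sentence_index": s_idx,
                        "token_start": m.span[0] - off,
                        "token_end": m.span[1] - off,
                    }
                )
            rec = {
                "doc_id": inst.doc_id,
                "sentences": inst.sentences(),
                "mentions": mentions,
                "label": inst.label,
            }
            fh.write(json.dumps(rec) + "\n")


def compute_position_features(
    instance: RelationInstance, max_distance: int = 128
) -> PositionFeatures:
    """Signed token distances to each entity mention head.

    ``d_role(i) = i - head_index(role)``: zero at the entity's own head,
    positive to its right. Values are clipped to ``[-max_distance,
    +max_distance]``. Roles with no mention (the gene slot of a binary
    instance) are filled with the +max_distance sentinel, i.e. "maximally
    far".
    """
    if max_distance <= 0:
        raise ValidationError("max_distance must be positive")
    n = len(instance.tokens)
    idx = np.arange(n)
    dists = {}
    for role in ROLES:
        if role in instance.mentions:
            d = idx - instance.mentions[role].head
            dists[role] = np.clip(d, -max_distance, max_distance)
        else:
            dists[role] = np.full(n, max_distance, dtype=int)
    return PositionFeatures(distances=dists, max_distance=max_distance)


def split_folds(
    n_or_dataset,
    k: int = 5,
    validation_size: int = 200,
    rng_seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """k-fold cross-validation partitions with a held-out validation slice.

    Test folds are disjoint and cover the dataset. From each fold's training
    portion a validation set is drawn uniformly at random; its size is
    ``min(validation_size, floor(0.05 * |train portion|))`` so that the
    protocol stays meaningful on small corpora. Partitions are a pure function
    of (dataset size, k, validation_size, seed).
    """
    n = n_or_dataset if isinstance(n_or_dataset, int) else len(n_or_dataset)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if n < k:
        raise ValidationError(f"dataset of size {n} cannot be split into {k} folds")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    test_folds = np.array_split(perm, k)
    parts = []
    for fold in test_folds:
        rest = np.setdiff1d(perm, fold, assume_unique=True)
        # reshuffle so validation draw is independent of setdiff1d's sort order
        rest = rest[rng.permutation(len(rest))]
        v = min(validation_size, int(0.05 * len(rest)))
        val, train = rest[:v], rest[v:]
        parts.append((np.sort(train), np.sort(val), np.sort(fold)))
    return parts
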