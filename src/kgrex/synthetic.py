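"""Synthetic corpora and knowledge graphs with known ground truth.

These generators make every stage of the pipeline testable offline:

* :func:`generate_kg` plants an exact (or noisy) additive-translation
  structure — true entity vectors with tails at ``h + r (+ noise)`` — so
  translation-model training has a recoverable ground truth.
* :func:`generate_corpus` plants lexical label signal (a class-specific
  trigger token near the drug mention, with probability ``signal_strength``)
  and/or knowledge-graph label signal (the label set to the KG relation
  linking the sampled drug–gene pair, with probability
  ``kg_signal_strength`` — text alone is then uninformative), over Zipfian
  filler text in one or two sentences.
* :func:`worked_example_fixture` returns the canonical two-sentence
  EGFR / L858E / gefitinib passage used to pin down the position-feature
  conventions.

Generators are pure functions of their specs: the same spec (seed included)
produces bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    MULTICLASS_LABELS,
    ROLES,
    Dataset,
    LabelScheme,
    Mention,
    RelationInstance,
    normalize_tokens,
)
from .errors import ValidationError
from .kg import KnowledgeGraph

_ROLE_PREFIX = {"drug": "DRUG", "gene": "GENE", "mutation": "MUT"}


@dataclass
class KGSpec:
    """Planted-translation knowledge-graph spec.

    Heads are drugs; tails belong to ``tail_role`` (gene by default, mutation
    for drug–mutation graphs). With ``exact_tails`` each (head, relation)
    pair creates a fresh tail entity at exactly ``h + r + noise``; otherwise
    the tail snaps to the nearest member of a pre-drawn pool of
    ``n_tail_pool`` entities. ``n_relations`` relation names are taken from
    the five-type interaction set.
    """

    n_drugs: int = 20
    n_relations: int = 4
    triples_per_relation: int = 15
    k_true: int = 8
    noise_sd: float = 0.0
    tail_role: str = "gene"
    exact_tails: bool = True
    n_tail_pool: int = 30
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_relations, self.triples_per_relation, self.k_true) <= 0:
            raise ValidationError("KGSpec counts must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not 1 <= self.n_relations <= len(MULTICLASS_LABELS):
            raise ValidationError("n_relations must be between 1 and 5")
        if self.triples_per_relation > self.n_drugs:
            raise ValidationError(
                "triples_per_relation cannot exceed n_drugs (heads are drawn "
                "without replacement per relation)"
            )
        if self.tail_role not in ("gene", "mutation"):
            raise ValidationError("tail_role must be 'gene' or 'mutation'")


def generate_kg(spec: KGSpec) -> tuple[KnowledgeGraph, dict]:
    """Plant a translation-structured KG; returns (graph, manifest).

    The manifest records the true vectors of every entity and relation and
    the planted triples, for parameter-recovery checks.
    """
    rng = np.random.default_rng(spec.rng_seed)
    k = spec.k_true
    relations = list(MULTICLASS_LABELS[: spec.n_relations])
    rel_true = {r: rng.normal(0, 1.0 / np.sqrt(k), k) for r in relations}

    true_vecs: dict[str, np.ndarray] = {}
    drugs = []
    for i in range(spec.n_drugs):
        name = f"{_ROLE_PREFIX['drug']}{i}"
        drugs.append(name)
        true_vecs[name] = rng.normal(0, 1.0 / np.sqrt(k), k)

    prefix = _ROLE_PREFIX[spec.tail_role]
    tail_pool = []
    if not spec.exact_tails:
        for i in range(spec.n_tail_pool):
            name = f"{prefix}{i}"
            tail_pool.append(name)
            true_vecs[name] = rng.normal(0, 1.0 / np.sqrt(k), k)

    kg = KnowledgeGraph(entities=[], relations=[], triples=set())
    planted = []
    tail_of: dict[tuple[str, str], str] = {}
    n_created = 0
    for rel in relations:
        heads = rng.choice(spec.n_drugs, size=spec.triples_per_relation, replace=False)
        for hi in heads:
            head = drugs[int(hi)]
            target = true_vecs[head] + rel_true[rel]
            if spec.noise_sd > 0:
                target = target + rng.normal(0, spec.noise_sd, k)
            if spec.exact_tails:
                tail = tail_of.get((head, rel))
                if tail is None:
                    tail = f"{prefix}{n_created}"
                    n_created += 1
                    true_vecs[tail] = target
                    tail_of[(head, rel)] = tail
            else:
                pool_mat = np.array([true_vecs[t] for t in tail_pool])
                tail = tail_pool[int(np.argmin(np.linalg.norm(pool_mat - target, axis=1)))]
            kg.add(head, rel, tail)
            planted.append((head, rel, tail))
    manifest = {
        "spec": spec,
        "relations": relations,
        "relation_vectors": rel_true,
        "entity_vectors": true_vecs,
        "planted_triples": planted,
    }
    return kg, manifest


@dataclass
class CorpusSpec:
    """Synthetic relation-instance corpus spec.

    Instances span two sentences with probability ``cross_sentence_prob``
    (0.7 by default, matching the roughly 70% cross-sentence share of
    curated drug–gene–mutation corpora); sentence lengths are uniform in
    ``sentence_length``. ``signal_strength`` plants a lexical trigger,
    ``kg_signal_strength`` a KG-derived label; at 0/0 the labels are pure
    noise.
    """

    n_instances: int = 200
    vocab_size: int = 300
    cross_sentence_prob: float = 0.7
    sentence_length: tuple[int, int] = (8, 16)
    scheme: LabelScheme = field(default_factory=LabelScheme.multiclass)
    signal_strength: float = 1.0
    kg_signal_strength: float = 0.0
    n_entities_per_role: int = 20
    trigger_window: int = 5
    rng_seed: int = 0

    def __post_init__(self):
        for p in (self.cross_sentence_prob, self.signal_strength, self.kg_signal_strength):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.sentence_length[0] < 4 or self.sentence_length[0] > self.sentence_length[1]:
            raise ValidationError("sentence_length range invalid (min 4)")
        if self.vocab_size <= len(self.scheme.classes):
            raise ValidationError("vocab too small to reserve trigger words")


def trigger_token(scheme: LabelScheme, label: str) -> str:
    return f"TRIG{scheme.index(label)}"


def _zipf_weights(n: int, a: float = 1.1) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** a
    return w / w.sum()


def generate_corpus(spec: CorpusSpec, kg: KnowledgeGraph | None = None) -> Dataset:
    """Generate a labelled corpus with planted signal; see module docstring."""
    if spec.kg_signal_strength > 0 and kg is None:
        raise ValidationError("kg_signal_strength > 0 requires a knowledge graph")
    rng = np.random.default_rng(spec.rng_seed)
    scheme = spec.scheme
    filler = [f"w{i:04d}" for i in range(spec.vocab_size)]
    weights = _zipf_weights(spec.vocab_size)

    pools = {
        role: [f"{_ROLE_PREFIX[role]}{i}" for i in range(spec.n_entities_per_role)]
        for role in ROLES
    }
    kg_triples = []
    if kg is not None:
        by_role = {role: [] for role in ROLES}
        for e in kg.entities:
            for role, pre in _ROLE_PREFIX.items():
                if e.startswith(pre):
                    by_role[role].append(e)
        for role in ROLES:
            if by_role[role]:
                pools[role] = by_role[role]
        kg_triples = [
            (kg.entities[t.head], kg.relations[t.relation], kg.entities[t.tail])
            for t in sorted(kg.triples, key=lambda t: (t.relation, t.head, t.tail))
        ]

    roles = scheme.required_roles
    instances = []
    for idx in range(spec.n_instances):
        n_sent = 2 if rng.random() < spec.cross_sentence_prob else 1
        lengths = rng.integers(spec.sentence_length[0], spec.sentence_length[1] + 1, n_sent)
        tokens = list(
            np.array(filler)[rng.choice(spec.vocab_size, size=int(lengths.sum()), p=weights)]
        )
        breaks = [0] if n_sent == 1 else [0, int(lengths[0])]
        n = len(tokens)

        # label and entity assignment
        entities = {role: pools[role][int(rng.integers(len(pools[role])))] for role in roles}
        if kg_triples and rng.random() < spec.kg_signal_strength:
            head, rel, tail = kg_triples[int(rng.integers(len(kg_triples)))]
            entities["drug"] = head
            tail_role = "gene" if tail.startswith(_ROLE_PREFIX["gene"]) else "mutation"
            if tail_role in entities:
                entities[tail_role] = tail
            label = scheme.map_label(rel)
        else:
            label = scheme.classes[int(rng.integers(len(scheme.classes)))]

        positions = rng.choice(n, size=len(roles), replace=False)
        mentions = {}
        for role, pos in zip(roles, positions):
            pos = int(pos)
            tokens[pos] = entities[role]
            mentions[role] = Mention(role=role, entity_id=entities[role], span=(pos, pos + 1))

        if rng.random() < spec.signal_strength:
            head = mentions["drug"].head
            lo = max(0, head - spec.trigger_window)
            hi = min(n, head + spec.trigger_window + 1)
            taken = {m.head for m in mentions.values()}
            slots = [i for i in range(lo, hi) if i not in taken]
            if slots:
                tokens[int(slots[int(rng.integers(len(slots)))])] = trigger_token(scheme, label)

        inst = RelationInstance(
            doc_id=f"synth{idx:05d}",
            tokens=tokens,
            sentence_breaks=breaks,
            mentions=mentions,
            label=label,
        )
        inst.validate(scheme)
        instances.append(inst)
    return Dataset(instances, scheme)


# the canonical passage: two sentences, three entity mentions
_EXAMPLE_SENTENCES = (
    "The deletion mutation on exon 19 of the EGFR gene was present in 16 "
    "patients, while the L858E point mutation on exon 21 was noted in 10.",
    "All patients were treated with gefitinib and showed a partial response.",
)


def worked_example_fixture() -> RelationInstance:
    """The two-sentence EGFR / L858E / gefitinib passage.

    Under whitespace tokenization with punctuation stripped, "treated" lands
    at flat index 30 with the gene at 8, the mutation at 17 and the drug at
    32 — fixing the signed-distance convention (22, 13, −2).
    """
    sentences = normalize_tokens(_EXAMPLE_SENTENCES)
    tokens, breaks = [], []
    for sent in sentences:
        breaks.append(len(tokens))
        tokens.extend(sent)
    mentions = {}
    for role, surface in (("gene", "EGFR"), ("mutation", "L858E"), ("drug", "gefitinib")):
        i = tokens.index(surface)
        mentions[role] = Mention(role=role, entity_id=surface, span=(i, i + 1))
    inst = RelationInstance(
        doc_id="worked-example",
        tokens=tokens,
        sentence_breaks=breaks,
        mentions=mentions,
        label="response",
    )
    inst.validate(LabelScheme.multiclass())
    return inst
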