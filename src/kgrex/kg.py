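"""Translation-model knowledge-graph embeddings.

A knowledge graph of drug–gene and drug–mutation facts is embedded so that
each relation acts as a vector translation from head to tail entity,
``h + r ≈ t``. Four variants are supported:

* **TransE** — score ``‖h + r − t‖_p`` directly in entity space.
* **TransH** — entities are first projected onto a relation-specific
  hyperplane with unit normal ``w_r`` before translating by ``d_r``.
* **TransR** — entities are mapped into relation space by a k×k matrix
  ``M_r``.
* **TransD** — dynamic rank-1-plus-identity mapping built from entity and
  relation projection vectors, ``M_re = r_p e_pᵀ + I``.

Training minimises the margin ranking loss ``Σ [γ + d(pos) − d(neg)]₊`` with
one filtered negative per positive, by minibatch gradient descent with
analytic gradients. Entity vectors are re-projected onto the unit ball after
every epoch, and TransH normals are kept at unit norm.

The classifier consumes *relation vectors*: differences of two entity
embeddings (gene − drug, mutation − drug) in entity space, with a zero vector
for entities absent from the graph.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import MULTICLASS_LABELS
from .errors import ParseError, ValidationError

VARIANTS = ("transE", "transH", "transR", "transD")
#: relation names admitted by default when reading triple files
DEFAULT_RELATIONS = frozenset(MULTICLASS_LABELS)


@dataclass(frozen=True)
class Triple:
    head: int
    relation: int
    tail: int


@dataclass
class KnowledgeGraph:
    entities: list[str]
    relations: list[str]
    triples: set[Triple] = field(default_factory=set)

    def __post_init__(self):
        self.entity_index = {e: i for i, e in enumerate(self.entities)}
        self.relation_index = {r: i for i, r in enumerate(self.relations)}
        for t in self.triples:
            self._check(t)

    def _check(self, t: Triple) -> None:
        if not (0 <= t.head < len(self.entities) and 0 <= t.tail < len(self.entities)):
            raise ValidationError(f"entity index out of range in {t}")
        if not 0 <= t.relation < len(self.relations):
            raise ValidationError(f"relation index out of range in {t}")

    def add(self, head: str, relation: str, tail: str) -> Triple:
        h = self.entity_index.setdefault(head, len(self.entities))
        if h == len(self.entities):
            self.entities.append(head)
        r = self.relation_index.setdefault(relation, len(self.relations))
        if r == len(self.relations):
            self.relations.append(relation)
        t = self.entity_index.setdefault(tail, len(self.entities))
        if t == len(self.entities):
            self.entities.append(tail)
        trip = Triple(h, r, t)
        self.triples.add(trip)
        return trip

    def triple_names(self) -> list[tuple[str, str, str]]:
        return [
            (self.entities[t.head], self.relations[t.relation], self.entities[t.tail])
            for t in sorted(self.triples, key=lambda t: (t.relation, t.head, t.tail))
        ]


def read_triples(
    path: str | Path, allowed_relations: frozenset[str] | None = DEFAULT_RELATIONS
) -> KnowledgeGraph:
    """Read a 3-column TSV of (head_id, relation, tail_id) facts.

    Vocabularies are built in first-seen order; duplicate lines collapse under
    set semantics. ``allowed_relations=None`` disables the relation-name check.
    """
    kg = KnowledgeGraph(entities=[], relations=[], triples=set())
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, got {len(cols)}"
                )
            head, rel, tail = cols
            if allowed_relations is not None and rel not in allowed_relations:
                raise ValidationError(f"{path}: line {lineno}: unknown relation {rel!r}")
            kg.add(head, rel, tail)
    return kg


def write_triples(kg: KnowledgeGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h, r, t in kg.triple_names():
            fh.write(f"{h}\t{r}\t{t}\n")


@dataclass
class TranslationParams:
    """Learned embeddings of one translation-model variant.

    ``ent``/``rel`` are the entity and relation tables (dim k). Variant
    extras: ``w`` holds TransH hyperplane normals; ``M`` the TransR k×k
    projection matrices; ``ent_p``/``rel_p`` the TransD projection vectors.
    """

    variant: str
    k: int
    entity_ids: list[str]
    relation_ids: list[str]
    ent: np.ndarray  # (|E|, k)
    rel: np.ndarray  # (|R|, k)
    margin: float = 1.0
    p: int = 2
    w: np.ndarray | None = None  # TransH (|R|, k), unit rows
    M: np.ndarray | None = None  # TransR (|R|, k, k)
    ent_p: np.ndarray | None = None  # TransD (|E|, k)
    rel_p: np.ndarray | None = None  # TransD (|R|, k)

    def __post_init__(self):
        self.entity_index = {e: i for i, e in enumerate(self.entity_ids)}

    def entity_vector(self, entity_id: str) -> np.ndarray:
        """Entity embedding, or zeros for an entity absent from the KG."""
        i = self.entity_index.get(entity_id)
        return self.ent[i].copy() if i is not None else np.zeros(self.k)


def init_params(
    kg: KnowledgeGraph,
    variant: str = "transE",
    k: int = 50,
    margin: float = 1.0,
    p: int = 2,
    rng: np.random.Generator | None = None,
) -> TranslationParams:
    """Uniform ±6/√k initialization; relation vectors L2-normalized once;
    TransR matrices start at identity."""
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    if k <= 0:
        raise ValidationError("k must be positive")
    rng = rng or np.random.default_rng(0)
    b = 6.0 / np.sqrt(k)
    nE, nR = len(kg.entities), len(kg.relations)
    ent = rng.uniform(-b, b, (nE, k))
    rel = rng.uniform(-b, b, (nR, k))
    rel /= np.maximum(np.linalg.norm(rel, axis=1, keepdims=True), 1e-12)
    params = TranslationParams(
        variant=variant,
        k=k,
        entity_ids=list(kg.entities),
        relation_ids=list(kg.relations),
        ent=ent,
        rel=rel,
        margin=margin,
        p=p,
    )
    if variant == "transH":
        w = rng.normal(size=(nR, k))
        params.w = w / np.linalg.norm(w, axis=1, keepdims=True)
    elif variant == "transR":
        params.M = np.repeat(np.eye(k)[None], nR, axis=0)
    elif variant == "transD":
        params.ent_p = rng.uniform(-0.1, 0.1, (nE, k))
        params.rel_p = rng.uniform(-0.1, 0.1, (nR, k))
    return params


def _project(params: TranslationParams, h: np.ndarray, r: np.ndarray, t: np.ndarray):
    """Variant-specific projected (head, tail) vectors for index arrays h, t
    under relations r. Returns (h_proj, t_proj) with shape (n, k)."""
    he, te = params.ent[h], params.ent[t]
    if params.variant == "transE":
        return he, te
    if params.variant == "transH":
        w = params.w[r]
        return he - np.sum(w * he, 1, keepdims=True) * w, te - np.sum(
            w * te, 1, keepdims=True
        ) * w
    if params.variant == "transR":
        M = params.M[r]  # (n, k, k); row-vector convention e @ M_r
        return np.einsum("ni,nij->nj", he, M), np.einsum("ni,nij->nj", te, M)
    # transD: e + (e_p · e) r_p  ==  (r_p e_pᵀ + I) e
    rp = params.rel_p[r]
    hp, tp = params.ent_p[h], params.ent_p[t]
    return (
        he + np.sum(hp * he, 1, keepdims=True) * rp,
        te + np.sum(tp * te, 1, keepdims=True) * rp,
    )


def score_batch(
    params: TranslationParams,
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
) -> np.ndarray:
    """Dissimilarity ``‖proj(h) + r − proj(t)‖_p`` for index arrays; lower is
    more plausible."""
    h, r, t = np.atleast_1d(h), np.atleast_1d(r), np.atleast_1d(t)
    nE, nR = params.ent.shape[0], params.rel.shape[0]
    if h.max(initial=-1) >= nE or t.max(initial=-1) >= nE or r.max(initial=-1) >= nR:
        raise ValidationError("triple index out of range")
    if h.min(initial=0) < 0 or t.min(initial=0) < 0 or r.min(initial=0) < 0:
        raise ValidationError("triple index out of range")
    hp, tp = _project(params, h, r, t)
    diff = hp + params.rel[r] - tp
    if params.p == 1:
        return np.abs(diff).sum(axis=1)
    return np.linalg.norm(diff, axis=1)


def score_triple(params: TranslationParams, triple: Triple) -> float:
    return float(
        score_batch(
            params,
            np.array([triple.head]),
            np.array([triple.relation]),
            np.array([triple.tail]),
        )[0]
    )


def sample_negative(
    kg: KnowledgeGraph,
    triple: Triple,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> Triple:
    """Corrupt one side of a triple, filtered against the true triple set.

    Head or tail is chosen with probability ½; the replacement entity is drawn
    uniformly. Corruptions that reproduce a known true triple (or the input)
    are rejected and resampled; after ``max_retries`` failures both sides are
    enumerated exhaustively before giving up.
    """
    nE = len(kg.entities)
    if nE < 2:
        raise ValidationError("need at least 2 entities to sample negatives")
    corrupt_head = rng.random() < 0.5
    for _ in range(max_retries):
        e = int(rng.integers(nE))
        cand = (
            Triple(e, triple.relation, triple.tail)
            if corrupt_head
            else Triple(triple.head, triple.relation, e)
        )
        if cand != triple and cand not in kg.triples:
            return cand
    for e in range(nE):  # tiny/dense KG fallback: deterministic sweep
        for cand in (
            Triple(e, triple.relation, triple.tail),
            Triple(triple.head, triple.relation, e),
        ):
            if cand != triple and cand not in kg.triples:
                return cand
    raise ValidationError("no valid corruption exists for this triple")


def margin_loss(
    params: TranslationParams,
    positives: list[Triple],
    negatives: list[Triple],
    gamma: float | None = None,
) -> float:
    """Mean hinge ``[γ + d(pos) − d(neg)]₊`` over aligned positive/negative
    pairs."""
    if len(positives) != len(negatives):
        raise ValidationError("positives and negatives must be aligned")
    gamma = params.margin if gamma is None else gamma
    hp = np.array([t.head for t in positives])
    rp = np.array([t.relation for t in positives])
    tp = np.array([t.tail for t in positives])
    hn = np.array([t.head for t in negatives])
    rn = np.array([t.relation for t in negatives])
    tn = np.array([t.tail for t in negatives])
    d_pos = score_batch(params, hp, rp, tp)
    d_neg = score_batch(params, hn, rn, tn)
    return float(np.maximum(0.0, gamma + d_pos - d_neg).mean())


def _norm_grad(diff: np.ndarray, p: int) -> np.ndarray:
    """∂‖diff‖_p/∂diff, rows of zeros where the norm vanishes."""
    if p == 1:
        return np.sign(diff)
    nrm = np.linalg.norm(diff, axis=1, keepdims=True)
    return np.where(nrm > 1e-12, diff / np.maximum(nrm, 1e-12), 0.0)


def _accumulate_grads(params, h, r, t, g, grads):
    """Scatter ∂loss/∂diff = g (n, k) into parameter gradients for the triple
    index arrays (h, r, t). The sign split (+ for head side, − for tail) is
    handled here."""
    he, te = params.ent[h], params.ent[t]
    np.add.at(grads["rel"], r, g)
    if params.variant == "transE":
        np.add.at(grads["ent"], h, g)
        np.add.at(grads["ent"], t, -g)
    elif params.variant == "transH":
        w = params.w[r]
        gh = g - np.sum(w * g, 1, keepdims=True) * w
        np.add.at(grads["ent"], h, gh)
        np.add.at(grads["ent"], t, -gh)
        # d/dw of gᵀ[(wᵀe)w] = (wᵀe)g + (gᵀw)e, head minus tail
        gw = -(
            np.sum(w * he, 1, keepdims=True) * g
            + np.sum(g * w, 1, keepdims=True) * he
        ) + (
            np.sum(w * te, 1, keepdims=True) * g
            + np.sum(g * w, 1, keepdims=True) * te
        )
        np.add.at(grads["w"], r, gw)
    elif params.variant == "transR":
        M = params.M[r]
        np.add.at(grads["ent"], h, np.einsum("nj,nij->ni", g, M))
        np.add.at(grads["ent"], t, -np.einsum("nj,nij->ni", g, M))
        np.add.at(grads["M"], r, np.einsum("ni,nj->nij", he - te, g))
    else:  # transD
        rp_ = params.rel_p[r]
        hp_, tp_ = params.ent_p[h], params.ent_p[t]
        gdot = np.sum(g * rp_, 1, keepdims=True)
        np.add.at(grads["ent"], h, g + gdot * hp_)
        np.add.at(grads["ent"], t, -(g + gdot * tp_))
        np.add.at(grads["ent_p"], h, gdot * he)
        np.add.at(grads["ent_p"], t, -gdot * te)
        np.add.at(
            grads["rel_p"],
            r,
            np.sum(hp_ * he, 1, keepdims=True) * g
            - np.sum(tp_ * te, 1, keepdims=True) * g,
        )


def train_embeddings(
    kg: KnowledgeGraph,
    variant: str = "transE",
    k: int = 50,
    gamma: float = 1.0,
    p: int = 2,
    epochs: int = 100,
    batch_size: int = 32,
    learning_rate: float = 0.1,
    rng_seed: int = 0,
    params: TranslationParams | None = None,
) -> TranslationParams:
    """Minibatch gradient descent on the margin ranking loss.

    One filtered negative is sampled per positive per step. Entity norms are
    re-projected onto the unit ball after each epoch. Deterministic given the
    seed (up to floating-point reduction order). ``epochs=0`` returns the
    initialization unchanged.
    """
    if not kg.triples:
        raise ValidationError("empty knowledge graph")
    if k <= 0 or epochs < 0:
        raise ValidationError("k must be positive and epochs non-negative")
    rng = np.random.default_rng(rng_seed)
    if params is None:
        params = init_params(kg, variant, k, gamma, p, rng)
    triples = sorted(kg.triples, key=lambda t: (t.relation, t.head, t.tail))
    n = len(triples)
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = [triples[i] for i in order[start : start + batch_size]]
            negs = [sample_negative(kg, t, rng) for t in batch]
            hp = np.array([t.head for t in batch])
            rp = np.array([t.relation for t in batch])
            tp = np.array([t.tail for t in batch])
            hn = np.array([t.head for t in negs])
            tn = np.array([t.tail for t in negs])

            php, ptp = _project(params, hp, rp, tp)
            phn, ptn = _project(params, hn, rp, tn)
            diff_p = php + params.rel[rp] - ptp
            diff_n = phn + params.rel[rp] - ptn
            if params.p == 1:
                d_pos, d_neg = np.abs(diff_p).sum(1), np.abs(diff_n).sum(1)
            else:
                d_pos, d_neg = np.linalg.norm(diff_p, axis=1), np.linalg.norm(
                    diff_n, axis=1
                )
            viol = (gamma + d_pos - d_neg) > 0
            if not viol.any():
                continue
            scale = 1.0 / len(batch)
            g_pos = _norm_grad(diff_p, params.p) * viol[:, None] * scale
            g_neg = -_norm_grad(diff_n, params.p) * viol[:, None] * scale

            grads = {"ent": np.zeros_like(params.ent), "rel": np.zeros_like(params.rel)}
            if params.variant == "transH":
                grads["w"] = np.zeros_like(params.w)
            elif params.variant == "transR":
                grads["M"] = np.zeros_like(params.M)
            elif params.variant == "transD":
                grads["ent_p"] = np.zeros_like(params.ent_p)
                grads["rel_p"] = np.zeros_like(params.rel_p)
            _accumulate_grads(params, hp, rp, tp, g_pos, grads)
            _accumulate_grads(params, hn, rp, tn, g_neg, grads)

            params.ent -= learning_rate * grads["ent"]
            params.rel -= learning_rate * grads["rel"]
            if params.variant == "transH":
                params.w -= learning_rate * grads["w"]
                params.w /= np.maximum(
                    np.linalg.norm(params.w, axis=1, keepdims=True), 1e-12
                )
            elif params.variant == "transR":
                params.M -= learning_rate * grads["M"]
            elif params.variant == "transD":
                params.ent_p -= learning_rate * grads["ent_p"]
                params.rel_p -= learning_rate * grads["rel_p"]
        # unit-ball projection of entity vectors, once per epoch
        nrm = np.linalg.norm(params.ent, axis=1, keepdims=True)
        params.ent = np.where(nrm > 1.0, params.ent / np.maximum(nrm, 1e-12), params.ent)
    return params


def relation_vector(
    params: TranslationParams, head_entity_id: str, tail_entity_id: str
) -> np.ndarray:
    """Entity-space relation vector ``E_tail − E_head``.

    Used as the classifier's side information: gene − drug and
    mutation − drug. If either entity is missing from the KG the zero vector
    is returned, contributing no side information.
    """
    hi = params.entity_index.get(head_entity_id)
    ti = params.entity_index.get(tail_entity_id)
    if hi is None or ti is None:
        return np.zeros(params.k)
    return params.ent[ti] - params.ent[hi]


def evaluate_link_prediction(
    params: TranslationParams,
    kg: KnowledgeGraph,
    heldout: list[Triple],
) -> dict[str, float]:
    """Filtered tail ranking: for each held-out triple, rank the true tail
    among all entities by score, excluding other known-true completions from
    the candidate list. Returns mean_rank, hits@1 and hits@10."""
    if not heldout:
        raise ValidationError("empty held-out set")
    nE = len(params.entity_ids)
    known: dict[tuple[int, int], set[int]] = {}
    for t in kg.triples | set(heldout):
        known.setdefault((t.head, t.relation), set()).add(t.tail)
    ranks = []
    all_tails = np.arange(nE)
    for trip in heldout:
        scores = score_batch(
            params,
            np.full(nE, trip.head),
            np.full(nE, trip.relation),
            all_tails,
        )
        exclude = known.get((trip.head, trip.relation), set()) - {trip.tail}
        mask = np.ones(nE, dtype=bool)
        mask[list(exclude)] = False
        true_score = scores[trip.tail]
        rank = 1 + int(np.sum(scores[mask] < true_score))
        ranks.append(rank)
    ranks = np.array(ranks, dtype=float)
    return {
        "mean_rank": float(ranks.mean()),
        "hits@1": float((ranks <= 1).mean()),
        "hits@10": float((ranks <= 10).mean()),
    }


def save_params(params: TranslationParams, out_dir: str | Path) -> None:
    """Persist arrays to ``embeddings.npz`` plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {"ent": params.ent, "rel": params.rel}
    for name in ("w", "M", "ent_p", "rel_p"):
        a = getattr(params, name)
        if a is not None:
            arrays[name] = a
    np.savez(out / "embeddings.npz", **arrays)
    manifest = {
        "variant": params.variant,
        "k": params.k,
        "margin": params.margin,
        "p": params.p,
        "entity_ids": params.entity_ids,
        "relation_ids": params.relation_ids,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_params(in_dir: str | Path) -> TranslationParams:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    arrays = np.load(in_dir / "embeddings.npz")
    return TranslationParams(
        variant=manifest["variant"],
        k=manifest["k"],
        entity_ids=manifest["entity_ids"],
        relation_ids=manifest["relation_ids"],
        ent=arrays["ent"],
        rel=arrays["rel"],
        margin=manifest["margin"],
        p=manifest["p"],
        w=arrays["w"] if "w" in arrays else None,
        M=arrays["M"] if "M" in arrays else None,
        ent_p=arrays["ent_p"] if "ent_p" in arrays else None,
        rel_p=arrays["rel_p"] if "rel_p" in arrays else None,
    )
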