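# kgrex

Knowledge-graph-augmented cross-sentence **n-ary relation extraction** for
drug–gene–mutation interactions.

Precision-medicine literature states facts like *"the L858E mutation of the
EGFR gene confers sensitivity to gefitinib"* across sentence boundaries, and
the relation is ternary: it binds a drug, a gene and a mutation at once.
`kgrex` classifies such multi-sentence passages into five interaction types —
*resistance or nonresponse*, *sensitivity*, *response*, *resistance*, *none*
(or a collapsed yes/no scheme for binary drug–mutation instances) — and
augments the text signal with prior knowledge from a biomedical knowledge
graph.

## Model

Each token *i* is embedded as the concatenation of a word vector and three
position embeddings indexed by the signed distances to the drug, gene and
mutation mention heads (`d_ρ(i) = i − head(ρ)`). A bidirectional LSTM encodes
the sequence; multihead scaled dot-product self-attention
(`softmax(QKᵀ/√d_head)·V`, heads concatenated and linearly mixed) draws
global dependencies across sentences; max-pooling over time yields a sentence
vector **B**.

Separately, a knowledge graph of `(drug, interaction, gene)` /
`(drug, interaction, mutation)` triples is embedded with a translation model
(TransE, TransH, TransR or TransD), trained with the margin ranking loss
`Σ [γ + ‖h + r − t‖ − ‖h′ + r − t′‖]₊` over filtered negative samples so
that each relation acts as a vector translation `h + r ≈ t`. The classifier
input is

```
Ǎ = [B ; E_gene − E_drug ; E_mutation − E_drug]
```

— entity-difference *relation vectors* supply the prior — followed by a
softmax layer trained with cross-entropy (Adam, lr 0.001, minibatches of 6,
best-validation snapshot). All neural layers are plain numpy with analytic
gradients, verified against finite differences in the test suite.

## Worked example

Train translation embeddings on a synthetic planted-translation knowledge
graph, then train the classifier on a corpus whose labels are knowable *only*
through the graph (the text is pure noise):

```python
import numpy as np
from kgrex import (CorpusSpec, KGSpec, LabelScheme, TrainConfig, evaluate,
                   generate_corpus, generate_kg, train_embeddings,
                   train_model, evaluate_link_prediction)

kg, manifest = generate_kg(KGSpec(n_drugs=25, n_relations=5,
                                  triples_per_relation=20, k_true=8, rng_seed=3))
kg_params = train_embeddings(kg, "transE", k=8, gamma=2.0, epochs=1000, rng_seed=3)
held = sorted(kg.triples, key=lambda t: (t.relation, t.head, t.tail))
print("link prediction:", evaluate_link_prediction(kg_params, kg, held))

spec = CorpusSpec(n_instances=600, scheme=LabelScheme.multiclass(),
                  signal_strength=0.0, kg_signal_strength=1.0, rng_seed=13)
data = generate_corpus(spec, kg)
perm = np.random.default_rng(7).permutation(600)
tr, va, te = data.subset(perm[:420]), data.subset(perm[420:480]), data.subset(perm[480:])

cfg = TrainConfig(word_dim=32, pos_dim=8, hidden=32, kg_dim=8,
                  max_distance=64, epochs=10, rng_seed=7)
rep_kg = evaluate(train_model(tr, va, kg_params, None, cfg), te)
rep_no = evaluate(train_model(tr, va, None, None, cfg), te)
print(f"accuracy with KG: {rep_kg.accuracy:.3f}  macro-F1: {rep_kg.macro_f1:.3f}")
print(f"accuracy without: {rep_no.accuracy:.3f}  macro-F1: {rep_no.macro_f1:.3f}")
```

Output (a few minutes on one CPU):

```
link prediction: {'mean_rank': 1.0, 'hits@1': 1.0, 'hits@10': 1.0}
accuracy with KG: 0.767  macro-F1: 0.678
accuracy without: 0.167  macro-F1: 0.059
```

The embedding recovers every planted triple exactly (filtered hits@1 = 1.0),
and attaching the KG relation vectors lifts five-class accuracy from chance
(≈ 0.17) to 0.77 — the knowledge-graph channel alone carries the label.

A CLI mirrors the library: `kgrex simulate`, `kgrex train-kg`,
`kgrex train-model`, `kgrex evaluate`, `kgrex cross-validate` (see
`kgrex --help`).

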