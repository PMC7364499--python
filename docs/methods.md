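# Methods

## Task and data model

An instance is a passage of one or two sentences containing exactly one
mention each of a drug, a gene and a mutation (drug and mutation only in
binary mode), labelled with the interaction type the passage expresses.
Instances arrive pre-annotated as JSON-lines with sentence-local token
coordinates; in memory the sentences are flattened to one token sequence
with recorded sentence starts, so spans can be mapped back losslessly.

Tokenization is whitespace splitting with edge punctuation
(`.,;:!?()"'` and typographic quotes) stripped; standalone punctuation
disappears. This is the convention under which the canonical
EGFR / L858E / gefitinib passage yields the distances (22, 13, −2) from
*"treated"* to the three mentions, which fixes two further conventions:

* **Sign:** `d = token_index − entity_head_index`, positive when the entity
  is to the token's left ("treated" is two tokens left of "gefitinib",
  hence −2).
* **Head anchoring:** multi-token mentions are anchored at their first
  token; anchoring is deterministic and base-invariant.

Distances are clipped to ±`max_distance` (default 128) to bound the
position-embedding tables. A role absent from an instance (the gene slot in
binary mode) takes the +`max_distance` sentinel, i.e. "maximally far".

## Knowledge-graph embeddings

The graph stores `(head, interaction, tail)` facts with set semantics, with
relation names drawn from the five interaction types. Scoring per variant
(lower = more plausible, `p ∈ {1, 2}`, default 2):

| variant | score |
|---|---|
| TransE | ‖h + r − t‖ |
| TransH | ‖(h − (w_rᵀh)w_r) + d_r − (t − (w_rᵀt)w_r)‖ |
| TransR | ‖hM_r + r − tM_r‖ |
| TransD | ‖(r_p h_pᵀ + I)h + r − (r_p t_pᵀ + I)t‖ |

Training minimises the margin ranking loss `[γ + d(pos) − d(neg)]₊`
(mean over pairs) by minibatch gradient descent with hand-derived analytic
gradients, one filtered negative per positive (head or tail corrupted with
probability ½ each, corruptions that are true triples rejected). Entity
vectors are re-projected onto the unit ball after every epoch; TransH
normals are renormalised to unit length after every update. Initialization
is uniform ±6/√k with relation vectors L2-normalised once; TransR matrices
start at identity; TransD projection vectors start small-uniform (±0.1) so
their gradients are non-zero from the first step.

Defaults: k = 50, γ = 1, p = 2, lr = 0.1, 100 epochs. The margin only
*separates* positives from negatives, so a fit tight enough for
entity-difference relation vectors to align with the learned relation
embedding needs a stronger push: parameter-recovery runs use γ = 2 and
1000 epochs, under which a noise-free planted-translation graph of 80
entities (k = 8) is recovered with filtered hits@1 = 1.0, mean positive
score < 0.05 and mean cosine ≥ 0.99 between `E_tail − E_head` and the
learned relation vector.

The classifier consumes relation vectors in **entity space**
(`E_gene − E_drug`, `E_mutation − E_drug`) for all variants, because the
concatenation layer subtracts entity representations directly; entities
absent from the graph contribute a zero vector, which is exactly the no-KG
baseline for that instance.

## Encoder

Token representation: word vector (dim 200) ⊕ three position embeddings
(dim 50 each) → 350 dims. Word vectors can be loaded from word2vec-text or
GloVe-text files (auto-detected); without a file, tables initialize
uniform ±0.05. Unknown words share a trainable OOV row.

The Bi-LSTM (200 units per direction → 400-dim contextual vectors) offers
two cell variants:

* `paper_literal` (default): `g = tanh(W_xg x + W_hg(i ⊙ h_prev) + b_g)`,
  `h = (1 − f) ⊙ h_prev + f ⊙ g`. The output gate and the memory cell
  `c = f ⊙ c_prev + i ⊙ g` are computed but do not feed `h`; the cell is a
  functional gated unit of the highway/GRU family. With the forget gate
  driven to 0 it copies state exactly.
* `standard`: the textbook LSTM, `h = o ⊙ tanh(c)`.

Both carry analytic gradients checked against central differences
(relative error < 1e−4). Which of the two the original experiments used is
undecidable from the published description alone, so both are first-class
and configurable; the synthetic benchmarks pass with the default.

Batching uses right padding with a mask; padded positions never influence
valid outputs (asserted to machine precision). Recurrent dropout (rate 0.5)
is variational: one inverted-dropout mask per sequence per direction,
applied to the hidden-state input of all gates, training only.

## Attention and pooling

Per head: `M_i = softmax(XW_iQ (XW_iK)ᵀ / √(d/h)) XW_iV` with projections of
shape d × (d/h) (d = 400, h = 4), concatenated and mixed by W (d × d). The
per-head scale √(d/h) is the default; √d is available (`scale_mode =
"model"`) since the printed description is ambiguous. The sentence vector is
the elementwise max over time (mean available); a 0.5 dropout is applied to
the pooled vector during training. Whether the original model pooled or used
an entity-anchored reduction is unstated; max over time is the conventional
reduction for relation classification and both modes are tested.

## Classifier and training protocol

`Ǎ = [B; R_dg; R_dm]` (400 + 50 + 50 = 500 dims at the defaults) → softmax.
Cross-entropy loss with the gold probability clamped at 1e−12 (clamps are
logged). Adam (lr 0.001, β = 0.9/0.999), minibatches of 6, 10 epochs,
global-norm gradient clipping at 5 to stabilise the recurrent net. After
each epoch the model is scored on the validation split and the
best-validation snapshot wins; with no validation data the final epoch wins.
Ties at argmax resolve to the lowest class index. One master seed fans out
(via `numpy.random.SeedSequence.spawn`) to initialization, dropout and
shuffling.

Cross-validation: k = 5 test folds, disjoint and exhaustive; from each
fold's training portion a validation set of
`min(200, ⌊0.05 · |train|⌋)` instances is drawn — 200 at the corpus scale
the protocol was designed for, proportionally smaller on desk-scale data.
"Mean accuracy" is the arithmetic mean of per-fold accuracies (pooling
predictions across folds would be the alternative reading; per-fold mean is
implemented).

Evaluation reports accuracy, macro-F1 (unweighted mean of per-class F1, 0
for undefined classes), the gold × predicted confusion matrix, and accuracy
within token-length buckets [0, 45), [45, 75), [75, ∞).

Binary mode ships with the KG channel off (`kg_for_binary = False`):
relation-typed triples would leak the yes/no label outright. The drug–gene
slot of a binary instance is always zero-filled.

## Synthetic generators

`generate_kg` plants additive-translation structure: true entity vectors
drawn N(0, 1/k) per coordinate, and for each relation a set of heads drawn
without replacement whose tails are *created* at exactly
`h_true + r_true (+ N(0, noise_sd²))`. This exact-tail construction is the
default because it makes parameter recovery well-posed; a snap-to-nearest
mode (`exact_tails=False`) instead reuses a pre-drawn tail pool. Heads are
drugs; tails are genes by default (`tail_role` switches to mutations).

`generate_corpus` emulates the profile of curated drug–gene–mutation
corpora without any linguistic realism: 1–2 sentences (two with probability
0.7, mirroring the ≈70% cross-sentence share of such corpora), filler
tokens drawn Zipf(1.1) over the vocabulary so that token-frequency skew and
OOV paths are exercised, single-token entity surfaces, and labels uniform
over the scheme. Two planted signals, independently switchable:

* **Lexical** (`signal_strength` s): with probability s a class-specific
  trigger token is placed within ±5 tokens of the drug mention. At s = 1 a
  bag-of-words rule is perfect; at s = 0 tokens are independent of labels.
* **Knowledge-graph** (`kg_signal_strength` g): with probability g the
  instance's drug–gene pair is sampled from the graph and the label set to
  their relation — the text alone is then uninformative, so the
  KG-ablation accuracy gap measures exactly the side-channel's value.

What passing these benchmarks does *not* show: robustness to real
biomedical syntax, negation, coreference, multi-token or duplicated entity
mentions, or noisy entity linking. The generators test the machinery, not
the linguistics.

## Numerical choices and problem sizes

Sigmoid is computed in the overflow-safe piecewise form. Softmax subtracts
the row max. Zero-norm difference vectors get zero gradient. The
gradient-descent reductions make training deterministic given the seed.

The shipped test suite and the worked example run at desk scale: layer
dimensions 32/8/32/8 (word/position/hidden/KG) on 600-instance corpora and
~80-entity graphs, sizes at which the trigger benchmark reaches ≥ 0.9
held-out accuracy, the null-signal control stays at chance, and the
KG-ablation gap exceeds 0.1 — the same qualitative behavior the
full-size defaults (Table of defaults above) are designed for.

## Known limitations

* The literal cell discards `o` and `c` on the output path; if the original
  authors intended a standard LSTM, the default variant differs from their
  system (switch with `gate_variant="standard"`).
* Entity mentions recorded in the input are authoritative; repeated surface
  occurrences of the same entity are not re-linked.
* No mining of triples from literature; the KG arrives as a TSV.
* Headline accuracies reported for the real curated corpus are out of reach
  here by design: they require that external corpus and long stochastic
  training runs.
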