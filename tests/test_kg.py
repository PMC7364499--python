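"""Knowledge-graph embeddings: scoring, negative sampling, training,
relation vectors and link prediction."""
import numpy as np
import pytest

from kgrex import (
    KnowledgeGraph,
    Triple,
    evaluate_link_prediction,
    margin_loss,
    read_triples,
    relation_vector,
    sample_negative,
    score_triple,
    train_embeddings,
    write_triples,
)
from kgrex.errors import ParseError, ValidationError
from kgrex.kg import TranslationParams, init_params, load_params, save_params


def make_params(ent, rel, variant="transE", p=2, **extras):
    ent = np.asarray(ent, dtype=float)
    rel = np.asarray(rel, dtype=float)
    return TranslationParams(
        variant=variant,
        k=ent.shape[1],
        entity_ids=[f"e{i}" for i in range(ent.shape[0])],
        relation_ids=[f"r{i}" for i in range(rel.shape[0])],
        ent=ent,
        rel=rel,
        p=p,
        **extras,
    )


class TestReadTriples:
    def test_single_record(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("gefitinib\tsensitivity\tEGFR\n")
        kg = read_triples(f)
        assert len(kg.entities) == 2 and len(kg.relations) == 1 and len(kg.triples) == 1

    def test_duplicates_collapse(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("a\tsensitivity\tb\na\tsensitivity\tb\n")
        assert len(read_triples(f).triples) == 1

    def test_wrong_column_count(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("a\tb\n")
        with pytest.raises(ParseError, match="3 tab-separated"):
            read_triples(f)

    def test_unknown_relation(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("a\tfrobnicates\tb\n")
        with pytest.raises(ValidationError, match="unknown relation"):
            read_triples(f)
        assert len(read_triples(f, allowed_relations=None).triples) == 1

    def test_generator_round_trip(self, planted_kg, tmp_path):
        kg, manifest = planted_kg
        f = tmp_path / "kg.tsv"
        write_triples(kg, f)
        back = read_triples(f)
        assert len(back.triples) == len(kg.triples) == len(manifest["planted_triples"])


class TestScoreTriple:
    def test_exact_translation_scores_zero(self):
        params = make_params([[1.0, 0.0], [1.0, 1.0]], [[0.0, 1.0]])
        assert score_triple(params, Triple(0, 0, 1)) == pytest.approx(0.0)

    def test_hand_computed_l2_norm(self):
        # h=(1,0), r=(0,1), t=(0,0) -> ||(1,1)|| = sqrt(2)
        params = make_params([[1.0, 0.0], [0.0, 0.0]], [[0.0, 1.0]])
        assert score_triple(params, Triple(0, 0, 1)) == pytest.approx(np.sqrt(2))

    def test_l1_norm(self):
        params = make_params([[1.0, 0.0], [0.0, 0.0]], [[0.0, 1.0]], p=1)
        assert score_triple(params, Triple(0, 0, 1)) == pytest.approx(2.0)

    def test_transr_identity_equals_transe(self, rng):
        ent = rng.normal(size=(6, 4))
        rel = rng.normal(size=(2, 4))
        pe = make_params(ent, rel)
        pr = make_params(ent, rel, variant="transR", M=np.repeat(np.eye(4)[None], 2, 0))
        for t in [Triple(0, 0, 1), Triple(2, 1, 5), Triple(4, 0, 3)]:
            assert score_triple(pr, t) == score_triple(pe, t)

    def test_rotation_invariance_l2(self, rng):
        ent = rng.normal(size=(5, 3))
        rel = rng.normal(size=(2, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = make_params(ent, rel)
        b = make_params(ent @ q, rel @ q)
        for t in [Triple(0, 0, 1), Triple(3, 1, 4)]:
            assert score_triple(a, t) == pytest.approx(score_triple(b, t), abs=1e-12)

    def test_index_out_of_range(self):
        params = make_params([[0.0, 0.0]], [[0.0, 0.0]])
        with pytest.raises(ValidationError):
            score_triple(params, Triple(0, 0, 5))


class TestSampleNegative:
    def test_two_entity_enumeration(self, rng):
        kg = KnowledgeGraph(entities=["a", "b"], relations=["sensitivity"],
                            triples={Triple(0, 0, 1)})
        seen = {sample_negative(kg, Triple(0, 0, 1), rng) for _ in range(200)}
        assert seen == {Triple(1, 0, 1), Triple(0, 0, 0)}

    def test_filter_and_side_balance(self, planted_kg, rng):
        kg, _ = planted_kg
        trip = next(iter(kg.triples))
        heads = 0
        n = 10_000
        for _ in range(n):
            neg = sample_negative(kg, trip, rng)
            assert neg not in kg.triples
            changed_head = neg.head != trip.head
            changed_tail = neg.tail != trip.tail
            assert changed_head != changed_tail  # exactly one side
            heads += changed_head
        assert abs(heads / n - 0.5) < 0.05

    def test_saturated_kg_errors(self, rng):
        kg = KnowledgeGraph(
            entities=["a", "b"],
            relations=["sensitivity"],
            triples={Triple(h, 0, t) for h in (0, 1) for t in (0, 1)},
        )
        with pytest.raises(ValidationError, match="no valid corruption"):
            sample_negative(kg, Triple(0, 0, 1), rng)


class TestMarginLoss:
    def params(self):
        # scores: (0,0,1)->0, (0,0,2)->sqrt(2), tunable by construction
        return make_params([[1.0, 0.0], [1.0, 1.0], [0.0, 0.0]], [[0.0, 1.0]])

    def test_satisfied_margin_is_zero(self):
        p = make_params([[0.0, 0.0], [0.0, 5.0]], [[0.0, 0.0]], margin=1.0)
        # pos (0,r,0): score 0; neg (0,r,1): score 5 >= margin
        assert margin_loss(p, [Triple(0, 0, 0)], [Triple(0, 0, 1)]) == 0.0

    def test_tie_gives_gamma(self):
        p = self.params()
        assert margin_loss(p, [Triple(0, 0, 1)], [Triple(0, 0, 1)], gamma=0.7) == pytest.approx(0.7)

    def test_arithmetic(self):
        # gamma=1, d(pos)=0.4, d(neg)=0.9 -> 0.5
        ent = np.array([[0.0], [0.4], [0.9]])
        p = make_params(ent, [[0.0]])
        assert margin_loss(p, [Triple(0, 0, 1)], [Triple(0, 0, 2)], gamma=1.0) == pytest.approx(0.5)

    def test_mismatched_lengths(self):
        p = self.params()
        with pytest.raises(ValidationError):
            margin_loss(p, [Triple(0, 0, 1)], [])

    def test_nonnegative(self, planted_kg, rng):
        kg, _ = planted_kg
        params = init_params(kg, "transE", k=8, rng=rng)
        pos = sorted(kg.triples, key=lambda t: (t.relation, t.head, t.tail))[:20]
        neg = [sample_negative(kg, t, rng) for t in pos]
        assert margin_loss(params, pos, neg) >= 0.0


class TestTrainEmbeddings:
    def test_zero_epochs_is_identity(self, planted_kg):
        kg, _ = planted_kg
        a = train_embeddings(kg, "transE", k=8, epochs=0, rng_seed=5)
        b = init_params(kg, "transE", k=8, rng=np.random.default_rng(5))
        assert np.array_equal(a.ent, b.ent) and np.array_equal(a.rel, b.rel)

    def test_loss_decreases_on_planted_kg(self, planted_kg):
        kg, _ = planted_kg
        rng = np.random.default_rng(0)
        triples = sorted(kg.triples, key=lambda t: (t.relation, t.head, t.tail))
        negs = [sample_negative(kg, t, rng) for t in triples]
        start = train_embeddings(kg, "transE", k=8, epochs=0, rng_seed=4)
        end = train_embeddings(kg, "transE", k=8, epochs=100, rng_seed=4)
        assert margin_loss(end, triples, negs) < margin_loss(start, triples, negs)

    @pytest.mark.parametrize("variant", ["transE", "transH", "transR", "transD"])
    def test_all_variants_improve(self, planted_kg, variant):
        kg, _ = planted_kg
        rng = np.random.default_rng(1)
        triples = sorted(kg.triples, key=lambda t: (t.relation, t.head, t.tail))
        negs = [sample_negative(kg, t, rng) for t in triples]
        start = train_embeddings(kg, variant, k=8, epochs=0, rng_seed=2)
        end = train_embeddings(kg, variant, k=8, epochs=60, rng_seed=2)
        assert margin_loss(end, triples, negs) < margin_loss(start, triples, negs)

    def test_constraints_after_training(self, planted_kg):
        kg, _ = planted_kg
        params = train_embeddings(kg, "transH", k=8, epochs=30, rng_seed=2)
        assert (np.linalg.norm(params.ent, axis=1) <= 1.0 + 1e-9).all()
        assert np.allclose(np.linalg.norm(params.w, axis=1), 1.0)

    def test_deterministic_given_seed(self, planted_kg):
        kg, _ = planted_kg
        a = train_embeddings(kg, "transE", k=8, epochs=20, rng_seed=11)
        b = train_embeddings(kg, "transE", k=8, epochs=20, rng_seed=11)
        assert np.array_equal(a.ent, b.ent)

    def test_invalid_arguments(self, planted_kg):
        kg, _ = planted_kg
        with pytest.raises(ValidationError):
            train_embeddings(kg, "transE", k=0)
        with pytest.raises(ValidationError):
            train_embeddings(KnowledgeGraph([], [], set()), "transE", k=4)


class TestRelationVector:
    def test_self_difference_is_zero(self):
        p = make_params([[1.0, 2.0]], [[0.0, 0.0]])
        assert np.array_equal(relation_vector(p, "e0", "e0"), np.zeros(2))

    def test_arithmetic(self):
        p = make_params([[0.0, 1.0], [1.0, 2.0]], [[0.0, 0.0]])
        assert np.array_equal(relation_vector(p, "e0", "e1"), np.array([1.0, 1.0]))

    def test_missing_entity_gives_zeros(self):
        p = make_params([[0.0, 1.0]], [[0.0, 0.0]])
        assert np.array_equal(relation_vector(p, "e0", "absent"), np.zeros(2))


class TestLinkPrediction:
    def test_perfect_ranking(self):
        # t = h + r exactly for the gold tails; distractor far away
        ent = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 5.0]])
        p = make_params(ent, [[1.0, 0.0]])
        kg = KnowledgeGraph(entities=["e0", "e1", "e2"], relations=["r0"], triples=set())
        res = evaluate_link_prediction(p, kg, [Triple(0, 0, 1)])
        assert res == {"mean_rank": 1.0, "hits@1": 1.0, "hits@10": 1.0}

    def test_single_entity_degenerate(self):
        p = make_params([[0.0, 0.0]], [[0.0, 0.0]])
        kg = KnowledgeGraph(entities=["e0"], relations=["r0"], triples=set())
        assert evaluate_link_prediction(p, kg, [Triple(0, 0, 0)])["mean_rank"] == 1.0

    def test_random_embeddings_mean_rank_near_half(self):
        ranks = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = make_params(rng.normal(size=(50, 4)), rng.normal(size=(1, 4)))
            kg = KnowledgeGraph([f"e{i}" for i in range(50)], ["r0"], set())
            held = [Triple(int(rng.integers(50)), 0, int(rng.integers(50))) for _ in range(40)]
            ranks.append(evaluate_link_prediction(p, kg, held)["mean_rank"])
        assert abs(np.mean(ranks) - 25.5) < 5

    def test_empty_heldout_rejected(self):
        p = make_params([[0.0]], [[0.0]])
        kg = KnowledgeGraph(["e0"], ["r0"], set())
        with pytest.raises(ValidationError):
            evaluate_link_prediction(p, kg, [])

    def test_filtered_excludes_known_tails(self):
        # two true tails for the same (h, r); each gets rank 1 when the other
        # is excluded from its candidate list
        ent = np.array([[0.0], [1.0], [1.0]])
        p = make_params(ent, [[1.0]])
        kg = KnowledgeGraph(["e0", "e1", "e2"], ["r0"],
                            {Triple(0, 0, 1), Triple(0, 0, 2)})
        res = evaluate_link_prediction(p, kg, [Triple(0, 0, 1), Triple(0, 0, 2)])
        assert res["hits@1"] == 1.0


def test_params_save_load_round_trip(planted_kg, tmp_path):
    kg, _ = planted_kg
    params = train_embeddings(kg, "transD", k=8, epochs=5, rng_seed=1)
    save_params(params, tmp_path / "out")
    back = load_params(tmp_path / "out")
    assert back.variant == "transD" and back.k == 8
    assert np.array_equal(back.ent, params.ent)
    assert np.array_equal(back.rel_p, params.rel_p)
    assert back.entity_ids == params.entity_ids
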