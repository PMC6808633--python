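"""Wang similarity, report scoring, and the sweep experiments."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ontonorm import (
    SimilarityConfig,
    SynthConfig,
    build_ancestry_sso,
    generate_lexicon_corpus,
    generate_ontology,
    run_pipeline,
    score_predictions,
    sweep_decay,
    sweep_reduction,
    train_word_embeddings,
    wang_similarity,
)
from ontonorm.projection import Prediction


def wang_oracle(onto, a, b, factor):
    """Memoization-free oracle: S_A(t) = max over directed a->t paths of
    factor**len(path), via exhaustive simple-path enumeration."""
    g = nx.DiGraph((c, p) for c, ps in onto.parents.items() for p in ps)
    g.add_nodes_from(onto.concepts)

    def s_values(x):
        out = {x: 1.0}
        for t in nx.descendants(g, x):
            best = max(
                factor ** (len(path) - 1)
                for path in nx.all_simple_paths(g, x, t)
            )
            out[t] = best
        return out

    sa, sb = s_values(a), s_values(b)
    shared = set(sa) & set(sb)
    return sum(sa[t] + sb[t] for t in shared) / (sum(sa.values()) + sum(sb.values()))


@pytest.fixture(scope="module")
def fixture50():
    """50-concept end-to-end fixture shared by the sweep tests."""
    cfg = SynthConfig(seed=3)
    onto = generate_ontology(cfg)
    lc = generate_lexicon_corpus(onto, cfg)
    emb = train_word_embeddings(lc.sentences, dimension=20, epochs=3, seed=3)
    return onto, lc, emb


class TestWangSimilarity:
    def test_identity_is_one(self, ch3, diamond):
        for onto in (ch3, diamond):
            for c in onto.concepts:
                assert wang_similarity(onto, c, c) == pytest.approx(1.0)

    def test_hand_value_leaf_parent(self, ch3):
        cfg = SimilarityConfig(0.5)
        assert wang_similarity(ch3, "OBT:0003", "OBT:0002", cfg) == pytest.approx(9 / 13)

    def test_hand_value_leaf_root(self, ch3):
        cfg = SimilarityConfig(0.5)
        assert wang_similarity(ch3, "OBT:0003", "OBT:0001", cfg) == pytest.approx(5 / 11)

    def test_decreases_along_chain(self, ch3):
        cfg = SimilarityConfig()
        assert wang_similarity(ch3, "OBT:0003", "OBT:0002", cfg) > wang_similarity(
            ch3, "OBT:0003", "OBT:0001", cfg
        )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_symmetric_on_random_dag(self, random_dag, seed):
        onto = random_dag(30, seed)
        cfg = SimilarityConfig()
        cs = sorted(onto.concepts)[::3]
        for a, b in itertools.combinations(cs, 2):
            assert wang_similarity(onto, a, b, cfg) == pytest.approx(
                wang_similarity(onto, b, a, cfg)
            )

    @pytest.mark.parametrize("seed,n", [(0, 12), (1, 20), (2, 30)])
    def test_matches_path_enumeration_oracle(self, random_dag, seed, n):
        onto = random_dag(n, seed)
        cfg = SimilarityConfig()
        for a, b in itertools.combinations(sorted(onto.concepts), 2):
            assert wang_similarity(onto, a, b, cfg) == pytest.approx(
                wang_oracle(onto, a, b, cfg.contribution_factor), abs=1e-9
            )

    def test_bounds(self, random_dag):
        onto = random_dag(25, 4)
        cfg = SimilarityConfig()
        cs = sorted(onto.concepts)
        for a, b in itertools.combinations(cs[::2], 2):
            s = wang_similarity(onto, a, b, cfg)
            assert 0.0 < s < 1.0  # equal to 1 iff identical

    def test_unknown_concept(self, ch3):
        with pytest.raises(KeyError):
            wang_similarity(ch3, "OBT:0001", "NOPE")

    def test_factor_domain(self):
        with pytest.raises(ValueError):
            SimilarityConfig(0.0)
        with pytest.raises(ValueError):
            SimilarityConfig(1.0)


class TestScorePredictions:
    def test_perfect_predictions(self, ch3):
        preds = [Prediction(c, [(c, 1.0)]) for c in ch3.concepts]
        refs = {c: {c} for c in ch3.concepts}
        rep = score_predictions(preds, refs, ch3)
        assert rep.semantic_score == 1.0
        assert rep.strict_score == 1.0
        assert rep.n_mentions == 3

    def test_near_miss_scores_semantic_only(self, ch3):
        preds = [Prediction("m", [("OBT:0002", 0.9)])]
        refs = {"m": {"OBT:0003"}}
        rep = score_predictions(preds, refs, ch3, SimilarityConfig(0.5))
        assert rep.semantic_score == pytest.approx(9 / 13)
        assert rep.strict_score == 0.0

    def test_no_vector_scores_zero(self, ch3):
        preds = [Prediction("m", [], status="no_vector")]
        rep = score_predictions(preds, {"m": {"OBT:0001"}}, ch3)
        assert rep.semantic_score == 0.0
        assert rep.strict_score == 0.0
        assert rep.n_no_vector == 1

    def test_multi_reference_takes_max(self, ch3):
        preds = [Prediction("m", [("OBT:0002", 0.8)])]
        refs = {"m": {"OBT:0003", "OBT:0002"}}
        rep = score_predictions(preds, refs, ch3)
        assert rep.semantic_score == 1.0
        assert rep.strict_score == 1.0

    def test_missing_reference_is_error(self, ch3):
        with pytest.raises(KeyError, match="ghost"):
            score_predictions([Prediction("ghost", [("OBT:0001", 1.0)])], {}, ch3)

    def test_strict_never_exceeds_semantic(self, random_dag):
        rng = np.random.default_rng(0)
        onto = random_dag(30, 7)
        cs = sorted(onto.concepts)
        preds, refs = [], {}
        for i in range(40):
            m = f"m{i}"
            preds.append(Prediction(m, [(cs[rng.integers(len(cs))], 1.0)]))
            refs[m] = {cs[rng.integers(len(cs))]}
        rep = score_predictions(preds, refs, onto)
        assert rep.strict_score <= rep.semantic_score


class TestSweeps:
    def test_decay_grid_has_eleven_rows(self, fixture50):
        onto, lc, emb = fixture50
        rows = sweep_decay(onto, lc.train, lc.heldout[:30], emb)
        assert len(rows) == 11
        assert [r["w"] for r in rows] == [round(0.1 * i, 1) for i in range(11)]
        for r in rows:
            assert r["strict_score"] <= r["semantic_score"]

    def test_sweep_at_w1_matches_standalone_ancestry(self, fixture50):
        onto, lc, emb = fixture50
        rows = sweep_decay(onto, lc.train, lc.heldout[:30], emb, grid=[1.0])
        rep = run_pipeline(
            onto, build_ancestry_sso(onto), emb, lc.train, lc.heldout[:30]
        )
        assert rows[0]["semantic_score"] == pytest.approx(rep.semantic_score)
        assert rows[0]["strict_score"] == pytest.approx(rep.strict_score)

    def test_svd_fraction_zero_is_identity(self, fixture50):
        onto, lc, emb = fixture50
        rows = sweep_reduction(
            onto, lc.train, lc.heldout[:30], emb, method="svd", fractions=[0.0]
        )
        rep = run_pipeline(
            onto, build_ancestry_sso(onto), emb, lc.train, lc.heldout[:30]
        )
        assert rows[0]["semantic_score"] == pytest.approx(rep.semantic_score, abs=1e-6)
        assert rows[0]["strict_score"] == pytest.approx(rep.strict_score, abs=1e-6)

    def test_reduction_row_shape(self, fixture50):
        onto, lc, emb = fixture50
        fractions = [0.0, 0.3, 0.6, 0.9]
        rows = sweep_reduction(
            onto, lc.train, lc.heldout[:20], emb, method="pca", fractions=fractions
        )
        assert [r["fraction"] for r in rows] == fractions
        for r in rows:
            assert r["strict_score"] <= r["semantic_score"]

    def test_bad_fraction_rejected(self, fixture50):
        onto, lc, emb = fixture50
        with pytest.raises(ValueError):
            sweep_reduction(
                onto, lc.train, lc.heldout[:5], emb, fractions=[1.0]
            )
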