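"""Tokenization, word-embedding training, term composition, training pairs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ontonorm import (
    AnnotationPair,
    SynthConfig,
    WordEmbeddings,
    build_training_pairs,
    generate_lexicon_corpus,
    generate_ontology,
    load_word2vec_text,
    save_word2vec_text,
    term_vector,
    tokenize,
    train_word_embeddings,
)
from ontonorm.word2vec import EmbeddingModel


@pytest.fixture(scope="module")
def tiny_corpus():
    cfg = SynthConfig(n_concepts=15, seed=5, sentences_per_concept=8)
    onto = generate_ontology(cfg)
    return onto, generate_lexicon_corpus(onto, cfg).sentences


def _manual_embeddings(vectors: dict[str, list[float]]) -> WordEmbeddings:
    words = sorted(vectors)
    vocab = {w: i for i, w in enumerate(words)}
    M = np.array([vectors[w] for w in words], dtype=float)
    return WordEmbeddings(EmbeddingModel(vocab=vocab, vectors=M, mode="skipgram"))


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Soil samples", ["soil", "samples"]),
            ("", []),
            ("gut‐flora (human)", ["gut", "flora", "human"]),
            ("pH 7.4", ["ph", "7", "4"]),
            ("E. coli", ["e", "coli"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected


class TestTraining:
    def test_contract(self, tiny_corpus):
        _, sentences = tiny_corpus
        emb = train_word_embeddings(sentences, dimension=20, epochs=2, seed=0)
        assert emb.dimension == 20
        assert emb.oov_policy == "skip"
        counts = {}
        for s in sentences:
            for w in s:
                counts[w] = counts.get(w, 0) + 1
        for w in counts:
            assert emb.get(w) is not None
            assert emb.get(w).shape == (20,)

    def test_min_count_filters(self, tiny_corpus):
        _, sentences = tiny_corpus
        emb = train_word_embeddings(sentences, dimension=8, min_count=5, epochs=1)
        counts = {}
        for s in sentences:
            for w in s:
                counts[w] = counts.get(w, 0) + 1
        for w, c in counts.items():
            assert (emb.get(w) is not None) == (c >= 5)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty corpus"):
            train_word_embeddings([[]], dimension=4)

    def test_deterministic(self, tiny_corpus):
        _, sentences = tiny_corpus
        a = train_word_embeddings(sentences, dimension=10, epochs=1, seed=42)
        b = train_word_embeddings(sentences, dimension=10, epochs=1, seed=42)
        assert np.array_equal(a.model.vectors, b.model.vectors)

    def test_skipgram_unseen_word_is_oov(self, tiny_corpus):
        _, sentences = tiny_corpus
        emb = train_word_embeddings(sentences, dimension=8, mode="skipgram", epochs=1)
        assert emb.get("zzzunseenzzz") is None

    def test_subword_unseen_word_gets_finite_vector(self, tiny_corpus):
        _, sentences = tiny_corpus
        emb = train_word_embeddings(sentences, dimension=8, mode="subword", epochs=1)
        some_word = emb.vocabulary[0]
        v = emb.get(some_word + "ish")
        assert v is not None
        assert v.shape == (8,)
        assert np.all(np.isfinite(v))

    def test_subword_trained_word_matches_training_representation(self, tiny_corpus):
        """Query path composes exactly the representation training used."""
        _, sentences = tiny_corpus
        emb = train_word_embeddings(sentences, dimension=8, mode="subword", epochs=1)
        m = emb.model
        for w in emb.vocabulary[:10]:
            bks = m.indexer.buckets(w)
            expected = (m.vectors[m.vocab[w]] + m.bucket_vectors[bks].sum(axis=0)) / (
                1 + len(bks)
            )
            assert np.allclose(emb.get(w), expected, atol=1e-12)

    def test_cbow_mode_trains(self, tiny_corpus):
        _, sentences = tiny_corpus
        emb = train_word_embeddings(sentences, dimension=8, mode="cbow", epochs=1)
        assert emb.mode == "cbow"
        assert emb.get(emb.vocabulary[0]) is not None


class TestTermVector:
    def test_mean_and_full_coverage(self):
        emb = _manual_embeddings({"a": [1, 0], "b": [0, 1]})
        v, cov = term_vector(emb, ["a", "b"])
        assert np.allclose(v, [0.5, 0.5])
        assert cov == 1.0

    def test_oov_token_skipped(self):
        emb = _manual_embeddings({"a": [1, 0]})
        v, cov = term_vector(emb, ["a", "unknown"])
        assert np.allclose(v, [1, 0])
        assert cov == 0.5

    def test_all_oov_zero_vector(self):
        emb = _manual_embeddings({"a": [1, 0]})
        v, cov = term_vector(emb, ["unknown"])
        assert np.array_equal(v, [0, 0])
        assert cov == 0.0

    def test_single_word_identity(self):
        emb = _manual_embeddings({"a": [3.0, -2.0]})
        v, cov = term_vector(emb, ["a"])
        assert np.array_equal(v, [3.0, -2.0])
        assert cov == 1.0

    def test_empty_tokens_rejected(self):
        emb = _manual_embeddings({"a": [1, 0]})
        with pytest.raises(ValueError):
            term_vector(emb, [])

    @settings(derandomize=True, max_examples=30)
    @given(perm=st.permutations(["a", "b", "c", "unknown"]))
    def test_permutation_invariant(self, perm):
        emb = _manual_embeddings({"a": [1, 0], "b": [0, 1], "c": [2, 2]})
        v0, c0 = term_vector(emb, ["a", "b", "c", "unknown"])
        v, c = term_vector(emb, list(perm))
        assert np.allclose(v, v0)
        assert c == c0


class TestTrainingPairs:
    def test_unsupervised_one_per_label(self, ch3):
        pairs = build_training_pairs(ch3, mode="unsupervised")
        assert len(pairs) == 3
        assert {p.source for p in pairs} == {"concept_label"}
        assert {p.concept_id for p in pairs} == set(ch3.concepts)

    def test_synonyms_included_and_ablatable(self, ch3_path):
        from ontonorm import read_obo

        onto = read_obo(ch3_path)  # OBT:0002 has synonym "dirt"
        with_syn = build_training_pairs(onto, mode="unsupervised")
        assert ("dirt", "concept_synonym") in {
            (p.surface, p.source) for p in with_syn
        }
        without = build_training_pairs(onto, mode="unsupervised", include_synonyms=False)
        assert all(p.source == "concept_label" for p in without)

    def test_multi_concept_annotation_expands(self, ch3):
        ann = [("soil sample", ["OBT:0002", "OBT:0003"])]
        pairs = build_training_pairs(ch3, ann, mode="supervised")
        assert len(pairs) == 2
        assert {p.concept_id for p in pairs} == {"OBT:0002", "OBT:0003"}
        assert all(p.tokens == ("soil", "sample") for p in pairs)

    def test_supervised_requires_annotations(self, ch3):
        with pytest.raises(ValueError, match="requires annotations"):
            build_training_pairs(ch3, None, mode="supervised")

    def test_unknown_concept_listed(self, ch3):
        with pytest.raises(ValueError, match="OBT:9999"):
            build_training_pairs(ch3, [("x", ["OBT:9999"])], mode="supervised")

    def test_both_concatenates(self, ch3):
        ann = [("clay", ["OBT:0003"])]
        pairs = build_training_pairs(ch3, ann, mode="both")
        assert len(pairs) == 4  # 1 supervised + 3 labels
        assert AnnotationPair("clay", ("clay",), "OBT:0003") in pairs


class TestWord2VecText:
    def test_round_trip(self, tiny_corpus, tmp_path):
        _, sentences = tiny_corpus
        emb = train_word_embeddings(sentences, dimension=6, epochs=1, seed=1)
        path = tmp_path / "vectors.txt"
        save_word2vec_text(emb, path)
        back = load_word2vec_text(path)
        assert back.dimension == 6
        assert back.vocabulary == emb.vocabulary
        for w in emb.vocabulary:
            assert np.array_equal(back.get(w), emb.get(w))
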