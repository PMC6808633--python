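"""Term vector spaces (SSC): word embeddings, multiword composition,
and (term, concept) training-pair assembly.

A term's vector is the unweighted mean of its available token vectors; the
fraction of tokens that had vectors is reported alongside as a coverage
flag so callers can distinguish a fully grounded mention from one that is
partially or entirely out of vocabulary.  Under skip-gram/CBOW an unseen
word simply has no vector (the classical OOV failure mode); the subword
mode composes a finite vector from hashed character n-grams instead, so
every query word is representable.

Training pairs come in two flavors: *supervised* pairs from corpus
annotations (surface form -> annotated concept), and *unsupervised* pairs
built from the ontology itself (concept label -> concept, plus synonyms),
which cost no annotation at all.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .ontology import Ontology
from .word2vec import EmbeddingModel, train_embeddings

__all__ = [
    "WordEmbeddings",
    "AnnotationPair",
    "tokenize",
    "train_word_embeddings",
    "term_vector",
    "build_training_pairs",
    "save_word2vec_text",
    "load_word2vec_text",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split on whitespace and punctuation; lowercase; keep digits."""
    if lowercase:
        text = text.lower()
    return _TOKEN_RE.findall(text)


@dataclass
class WordEmbeddings:
    """Word -> vector mapping with an explicit out-of-vocabulary policy.

    ``oov_policy`` is ``"subword"`` exactly when the backing model was
    trained in subword mode; otherwise unseen words are skipped.
    """

    model: EmbeddingModel

    @property
    def dimension(self) -> int:
        return self.model.dimension

    @property
    def mode(self) -> str:
        return self.model.mode

    @property
    def oov_policy(self) -> str:
        return "subword" if self.model.mode == "subword" else "skip"

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self.model.vocab)

    def __contains__(self, word: str) -> bool:
        return word in self.model.vocab

    def get(self, word: str) -> np.ndarray | None:
        """Vector for ``word`` or None when OOV under the skip policy."""
        return self.model.word_vector(word)


def train_word_embeddings(
    corpus,
    dimension: int = 50,
    mode: str = "skipgram",
    window: int = 5,
    min_count: int = 1,
    epochs: int = 5,
    seed: int = 0,
) -> WordEmbeddings:
    """Train embeddings on an iterable of token lists.

    ``mode`` is one of ``skipgram``, ``cbow``, ``subword``; the subword
    mode additionally supports querying unseen words via character n-grams
    (range 3-6 with word-boundary markers).
    """
    model = train_embeddings(
        corpus,
        dimension=dimension,
        mode=mode,
        window=window,
        min_count=min_count,
        epochs=epochs,
        seed=seed,
    )
    return WordEmbeddings(model)


def term_vector(emb: WordEmbeddings, tokens: list[str]) -> tuple[np.ndarray, float]:
    """Mean of the available token vectors, plus coverage in [0, 1].

    Zero coverage returns the zero vector: the caller must treat such a
    term as unpredictable rather than trusting a vector of noise.
    """
    if not tokens:
        raise ValueError("term_vector requires a non-empty token list")
    vecs = [v for v in (emb.get(t) for t in tokens) if v is not None]
    if not vecs:
        return np.zeros(emb.dimension), 0.0
    return np.mean(vecs, axis=0), len(vecs) / len(tokens)


@dataclass(frozen=True)
class AnnotationPair:
    """A surface form linked to one concept, with its provenance."""

    surface: str
    tokens: tuple[str, ...]
    concept_id: str
    source: str = "corpus_annotation"  # | concept_label | concept_synonym

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError(f"annotation {self.surface!r} has no tokens")


def build_training_pairs(
    onto: Ontology,
    annotations: list | None = None,
    mode: str = "unsupervised",
    include_synonyms: bool = True,
) -> list[AnnotationPair]:
    """Assemble (term, concept) pairs for projection training.

    ``supervised`` uses the given annotations, expanding a multi-concept
    annotation into one pair per concept.  ``unsupervised`` needs only the
    ontology: one pair per concept label, plus one per synonym unless
    disabled.  ``both`` concatenates the two.
    """
    if mode not in ("supervised", "unsupervised", "both"):
        raise ValueError(f"unknown mode: {mode!r}")
    pairs: list[AnnotationPair] = []
    if mode in ("supervised", "both"):
        if not annotations:
            raise ValueError("supervised mode requires annotations")
        unknown = sorted(
            {cid for a in annotations for cid in _concept_ids(a)} - onto.concepts
        )
        if unknown:
            raise ValueError(f"annotations reference unknown concepts: {unknown}")
        for a in annotations:
            surface = a.surface if hasattr(a, "surface") else a[0]
            tokens = tuple(
                a.tokens if getattr(a, "tokens", None) else tokenize(surface)
            )
            for cid in _concept_ids(a):
                pairs.append(AnnotationPair(surface, tokens, cid, "corpus_annotation"))
    if mode in ("unsupervised", "both"):
        for c in onto.order:
            label = onto.labels.get(c, c)
            pairs.append(
                AnnotationPair(label, tuple(tokenize(label)), c, "concept_label")
            )
            if include_synonyms:
                for syn in onto.synonyms.get(c, []):
                    toks = tuple(tokenize(syn))
                    if toks:
                        pairs.append(AnnotationPair(syn, toks, c, "concept_synonym"))
    return pairs


def _concept_ids(a) -> list[str]:
    if hasattr(a, "concept_ids"):
        return list(a.concept_ids)
    if hasattr(a, "concept_id"):
        return [a.concept_id]
    return list(a[1]) if isinstance(a[1], (list, tuple, set)) else [a[1]]


def save_word2vec_text(emb: WordEmbeddings, path) -> None:
    """Write the classical word2vec text format (header: vocab dim)."""
    words = emb.vocabulary
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {emb.dimension}\n")
        for w in words:
            vec = emb.model.vectors[emb.model.vocab[w]]
            fh.write(w + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def load_word2vec_text(path) -> WordEmbeddings:
    """Read word2vec text format into a skip-policy WordEmbeddings."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        n, dim = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        vectors = np.zeros((n, dim))
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split(" ")
            vocab[parts[0]] = i
            vectors[i] = [float(x) for x in parts[1 : dim + 1]]
    if len(vocab) != n:
        raise ValueError(f"header promised {n} words, file has {len(vocab)}")
    return WordEmbeddings(EmbeddingModel(vocab=vocab, vectors=vectors, mode="skipgram"))
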