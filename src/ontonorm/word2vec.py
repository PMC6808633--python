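"""Minimal word2vec-family trainer: skip-gram, CBOW, and a subword variant.

Implements the negative-sampling training objective with plain numpy SGD.
It is deliberately small: the package trains on desk-scale corpora (a few
hundred to a few thousand sentences) and on random-walk "sentences" over
ontology graphs, where a dependency-free deterministic trainer matters more
than throughput.

The subword mode follows the fastText idea: each word is a bag of character
n-grams (3--6 by default, with ``<`` and ``>`` boundary markers); a word's
input vector is the mean of its own vector and its n-gram vectors, and an
*unseen* word can still be embedded from its n-grams alone.  N-grams are
hashed into a fixed number of buckets with FNV-1a, so any query word maps to
finite vectors.

Determinism contract: a fixed seed and the (implicit) single-worker
execution give byte-identical embeddings across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SubwordIndexer", "EmbeddingModel", "train_embeddings"]

_NEG_TABLE_SIZE = 1_000_000


def _fnv1a(data: bytes) -> int:
    h = 0xCBF29CE484222325
    for b in data:
        h ^= b
        h = (h * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


@dataclass(frozen=True)
class SubwordIndexer:
    """Maps a word to hashed character n-gram bucket indices."""

    n_min: int = 3
    n_max: int = 6
    n_buckets: int = 1 << 16

    def ngrams(self, word: str) -> list[str]:
        wrapped = f"<{word}>"
        out = []
        for n in range(self.n_min, self.n_max + 1):
            out.extend(wrapped[i : i + n] for i in range(len(wrapped) - n + 1))
        return out

    def buckets(self, word: str) -> np.ndarray:
        grams = self.ngrams(word)
        return np.array(
            [_fnv1a(g.encode("utf-8")) % self.n_buckets for g in grams], dtype=np.int64
        )


@dataclass
class EmbeddingModel:
    """Trained input vectors plus optional subword bucket vectors."""

    vocab: dict[str, int]
    vectors: np.ndarray  # (V, dim) input vectors
    mode: str  # skipgram | cbow | subword
    bucket_vectors: np.ndarray | None = None
    indexer: SubwordIndexer = field(default_factory=SubwordIndexer)

    @property
    def dimension(self) -> int:
        return int(self.vectors.shape[1])

    def word_vector(self, word: str) -> np.ndarray | None:
        """Vector for ``word``; None if OOV and no subword information."""
        idx = self.vocab.get(word)
        if self.mode != "subword":
            return self.vectors[idx].copy() if idx is not None else None
        bks = self.indexer.buckets(word)
        assert self.bucket_vectors is not None
        if idx is not None:
            parts = np.vstack([self.vectors[idx], self.bucket_vectors[bks]])
        elif len(bks):
            parts = self.bucket_vectors[bks]
        else:  # degenerate: word shorter than the smallest n-gram
            return np.zeros(self.dimension)
        return parts.mean(axis=0)


def _build_vocab(sentences, min_count: int) -> tuple[dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for sent in sentences:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    words = sorted(w for w, c in counts.items() if c >= min_count)
    vocab = {w: i for i, w in enumerate(words)}
    freqs = np.array([counts[w] for w in words], dtype=np.float64)
    return vocab, freqs


def _negative_table(freqs: np.ndarray) -> np.ndarray:
    p = freqs**0.75
    p /= p.sum()
    counts = np.maximum(1, np.round(p * _NEG_TABLE_SIZE).astype(np.int64))
    return np.repeat(np.arange(len(freqs), dtype=np.int64), counts)


def train_embeddings(
    sentences,
    dimension: int = 50,
    mode: str = "skipgram",
    window: int = 5,
    min_count: int = 1,
    negative: int = 5,
    epochs: int = 5,
    alpha: float = 0.025,
    seed: int = 0,
    indexer: SubwordIndexer | None = None,
) -> EmbeddingModel:
    """Train an :class:`EmbeddingModel` on tokenized sentences.

    Parameters mirror the classical tool: ``window`` is the maximum
    one-sided context size (sampled uniformly per position), ``negative``
    the number of noise samples per positive pair, ``alpha`` the initial
    learning rate (decayed linearly to 1e-4 of itself).
    """
    if mode not in ("skipgram", "cbow", "subword"):
        raise ValueError(f"unknown mode: {mode!r}")
    sentences = [list(s) for s in sentences]
    if not any(sentences):
        raise ValueError("empty corpus: no tokens to train on")
    vocab, freqs = _build_vocab(sentences, min_count)
    if not vocab:
        raise ValueError(f"no word reaches min_count={min_count}")
    V = len(vocab)
    rng = np.random.default_rng(seed)
    W = (rng.random((V, dimension)) - 0.5) / dimension  # input vectors
    C = np.zeros((V, dimension))  # output vectors
    neg_table = _negative_table(freqs)
    indexer = indexer or SubwordIndexer()

    B = None
    word_buckets: list[np.ndarray] = []
    if mode == "subword":
        B = (rng.random((indexer.n_buckets, dimension)) - 0.5) / dimension
        inv = {i: w for w, i in vocab.items()}
        word_buckets = [indexer.buckets(inv[i]) for i in range(V)]

    encoded = [
        np.array([vocab[w] for w in sent if w in vocab], dtype=np.int64)
        for sent in sentences
    ]
    encoded = [s for s in encoded if len(s)]

    total_steps = max(1, epochs * sum(len(s) for s in encoded))
    step = 0
    for _epoch in range(epochs):
        for sent in encoded:
            n = len(sent)
            radii = rng.integers(1, window + 1, size=n)
            for i in range(n):
                lr = alpha * max(1e-4, 1.0 - step / total_steps)
                step += 1
                lo, hi = max(0, i - radii[i]), min(n, i + radii[i] + 1)
                ctx = np.concatenate([sent[lo:i], sent[i + 1 : hi]])
                if not len(ctx):
                    continue
                center = sent[i]
                if mode == "cbow":
                    h = W[ctx].mean(axis=0)
                    negs = neg_table[rng.integers(0, len(neg_table), size=negative)]
                    targets = np.concatenate([[center], negs])
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    scores = C[targets] @ h
                    g = lr * (labels - 1.0 / (1.0 + np.exp(-scores)))
                    gh = g @ C[targets]
                    C[targets] += np.outer(g, h)
                    W[ctx] += gh / len(ctx)
                else:  # skipgram / subword: predict each context from center
                    if mode == "subword":
                        bks = word_buckets[center]
                        m = 1 + len(bks)
                        h = (W[center] + B[bks].sum(axis=0)) / m
                    else:
                        h = W[center]
                    negs = neg_table[
                        rng.integers(0, len(neg_table), size=negative * len(ctx))
                    ].reshape(len(ctx), negative)
                    for j, cw in enumerate(ctx):
                        targets = np.concatenate([[cw], negs[j]])
                        labels = np.zeros(len(targets))
                        labels[0] = 1.0
                        scores = C[targets] @ h
                        g = lr * (labels - 1.0 / (1.0 + np.exp(-scores)))
                        gh = g @ C[targets]
                        C[targets] += np.outer(g, h)
                        if mode == "subword":
                            W[center] += gh / m
                            B[bks] += gh / m
                        else:
                            W[center] += gh

    return EmbeddingModel(
        vocab=vocab, vectors=W, mode=mode, bucket_vectors=B, indexer=indexer
    )
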