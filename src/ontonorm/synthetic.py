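"""Synthetic ontologies, lexicons, corpora, annotations and planted
projection instances.

Everything here is a pure function of its configuration and seed, so
fixtures are regenerated byte-identically at test time instead of being
shipped as data files.  The generators emulate the shape of a habitat
normalization task: a rooted is-a DAG of concepts, a concept-specific
vocabulary, a corpus whose sentences mix a concept's words with its
parent's words (so that distributional similarity mirrors ontological
proximity — the premise the projection method relies on), and standoff
annotations linking sampled surface forms to their generating concepts.

What this does **not** emulate: real biomedical morphology and typography,
ambiguous surface forms shared between concepts, or discontinuous
mentions.  Scores obtained on this data demonstrate that the machinery
recovers planted structure, not performance on real corpora.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .concept_space import ConceptVectorSpace
from .ontology import Ontology
from .term_space import AnnotationPair

__all__ = [
    "SynthConfig",
    "LexiconCorpus",
    "generate_ontology",
    "generate_lexicon_corpus",
    "generate_planted_instance",
    "export_fixture",
]

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for all generators.

    ``max_parents == 1`` yields a tree; larger values a DAG.  ``mix_ratio``
    is the probability that a corpus token is drawn from the parent
    concept's vocabulary instead of the concept's own.  ``oov_fraction``
    of held-out mentions use a word absent from the training corpus, to
    exercise the out-of-vocabulary path.
    """

    n_concepts: int = 50
    max_parents: int = 2
    words_per_concept: int = 3
    n_mentions: int = 200
    embed_dim: int = 20
    noise_sigma: float = 0.0
    seed: int = 0
    sentences_per_concept: int = 12
    sentence_length: int = 8
    mix_ratio: float = 0.3
    heldout_fraction: float = 0.3
    oov_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_concepts < 1 or self.max_parents < 1:
            raise ValueError("n_concepts and max_parents must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _pseudo_word(rng: np.random.Generator, used: set[str]) -> str:
    """Pronounceable pseudo-word, regenerated until globally unique."""
    while True:
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(n_syll)
        )
        if word not in used:
            used.add(word)
            return word


def _concept_id(i: int) -> str:
    return f"SYN:{i:06d}"


def generate_ontology(cfg: SynthConfig) -> Ontology:
    """Random rooted DAG: concept i>0 draws 1..max_parents earlier parents.

    Parents are drawn from already-created concepts, so the construction
    order is a topological order and acyclicity holds by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    used: set[str] = set()
    concepts = [_concept_id(i) for i in range(cfg.n_concepts)]
    labels = {c: _pseudo_word(rng, used) for c in concepts}
    synonyms = {c: [] for c in concepts}
    parents: dict[str, frozenset[str]] = {concepts[0]: frozenset()}
    for i in range(1, cfg.n_concepts):
        k = int(rng.integers(1, min(cfg.max_parents, i) + 1))
        picks = rng.choice(i, size=k, replace=False)
        parents[concepts[i]] = frozenset(concepts[j] for j in picks)
    return Ontology(
        concepts=frozenset(concepts),
        labels=labels,
        synonyms=synonyms,
        parents=parents,
    )


@dataclass
class LexiconCorpus:
    """Corpus plus annotations split into training and held-out parts."""

    sentences: list[list[str]]
    train: list[AnnotationPair]
    heldout: list[AnnotationPair]
    lexicon: dict[str, list[str]] = field(default_factory=dict)

    @property
    def annotations(self) -> list[AnnotationPair]:
        return self.train + self.heldout


def generate_lexicon_corpus(onto: Ontology, cfg: SynthConfig) -> LexiconCorpus:
    """Planted lexicon, mixed-vocabulary corpus, and annotations.

    Each concept owns ``words_per_concept`` pseudo-words plus one reserved
    word that never enters the corpus (the OOV probe).  Sentences for a
    concept draw each token from its own vocabulary with probability
    ``1 - mix_ratio`` and from a parent's with probability ``mix_ratio``.
    Mentions are sampled surface forms (1-2 of the concept's words); the
    last ``heldout_fraction`` are the evaluation split, and within it
    ``oov_fraction`` of mentions use the reserved OOV word.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    order = onto.order
    used = set(onto.labels.values())
    lexicon = {
        c: [_pseudo_word(rng, used) for _ in range(cfg.words_per_concept)]
        for c in order
    }
    oov_word = {c: _pseudo_word(rng, used) for c in order}

    sentences: list[list[str]] = []
    for c in order:
        own = lexicon[c] + [onto.labels[c]]
        ps = sorted(onto.parents.get(c, ()))
        parent_pool = [w for p in ps for w in lexicon[p] + [onto.labels[p]]]
        for _ in range(cfg.sentences_per_concept):
            sent = []
            for _ in range(cfg.sentence_length):
                pool = (
                    parent_pool
                    if parent_pool and rng.random() < cfg.mix_ratio
                    else own
                )
                sent.append(pool[int(rng.integers(len(pool)))])
            sentences.append(sent)

    n_held = int(round(cfg.n_mentions * cfg.heldout_fraction))
    n_oov = int(round(n_held * cfg.oov_fraction))
    annotations: list[AnnotationPair] = []
    for i in range(cfg.n_mentions):
        c = order[int(rng.integers(len(order)))]
        heldout = i >= cfg.n_mentions - n_held
        if heldout and i >= cfg.n_mentions - n_oov:
            tokens = (oov_word[c],)
        else:
            k = int(rng.integers(1, min(2, cfg.words_per_concept) + 1))
            picks = rng.choice(cfg.words_per_concept, size=k, replace=False)
            tokens = tuple(lexicon[c][j] for j in picks)
        annotations.append(
            AnnotationPair(
                surface=" ".join(tokens),
                tokens=tokens,
                concept_id=c,
                source="corpus_annotation",
            )
        )
    split = cfg.n_mentions - n_held
    return LexiconCorpus(
        sentences=sentences,
        train=annotations[:split],
        heldout=annotations[split:],
        lexicon=lexicon,
    )


def generate_planted_instance(
    onto: Ontology, sso: ConceptVectorSpace, cfg: SynthConfig
) -> tuple[list[tuple[np.ndarray, str]], np.ndarray]:
    """Planted linear instance: x_c = G y_c + Gaussian noise, one per concept.

    ``G`` (embed_dim x SSO dim) has i.i.d. standard normal entries scaled
    by 1/sqrt(dim) — well-conditioned with overwhelming probability — and
    is returned so recovery tests can compare against the truth.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    d_sso = sso.dimension
    G = rng.standard_normal((cfg.embed_dim, d_sso)) / math.sqrt(d_sso)
    pairs = []
    for c in sso.concepts:
        x = G @ sso.vector(c)
        if cfg.noise_sigma > 0:
            x = x + rng.normal(scale=cfg.noise_sigma, size=cfg.embed_dim)
        pairs.append((x, c))
    return pairs, G


def export_fixture(onto: Ontology, lc: LexiconCorpus, out_dir) -> dict[str, str]:
    """Write the generated data in its on-disk formats.

    OBO for the ontology, one-sentence-per-line text for the corpus, and
    .a1/.a2 standoff for the held-out annotations (the corpus text is
    synthetic, so mention offsets index into a constructed document).
    Returns the mapping of role -> written path.
    """
    import os

    from .ontology import write_obo
    from .standoff import Mention, Normalization, write_a1, write_a2

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "obo": os.path.join(out_dir, "ontology.obo"),
        "corpus": os.path.join(out_dir, "corpus.txt"),
        "txt": os.path.join(out_dir, "doc.txt"),
        "a1": os.path.join(out_dir, "doc.a1"),
        "a2": os.path.join(out_dir, "doc.a2"),
    }
    write_obo(onto, paths["obo"])
    with open(paths["corpus"], "w", encoding="utf-8") as fh:
        for sent in lc.sentences:
            fh.write(" ".join(sent) + "\n")
    mentions, norms = [], []
    offset = 0
    doc_parts = []
    for i, ann in enumerate(lc.annotations, start=1):
        start = offset
        end = start + len(ann.surface)
        doc_parts.append(ann.surface)
        offset = end + 1  # single separating space
        mentions.append(
            Mention(
                entity_id=f"T{i}",
                type="Habitat",
                spans=((start, end),),
                surface=ann.surface,
            )
        )
        norms.append(
            Normalization(
                norm_id=f"N{i}",
                entity_id=f"T{i}",
                resource="SyntheticOntology",
                referent=ann.concept_id,
            )
        )
    with open(paths["txt"], "w", encoding="utf-8") as fh:
        fh.write(" ".join(doc_parts) + "\n")
    write_a1(mentions, paths["a1"])
    write_a2(norms, paths["a2"])
    return paths
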