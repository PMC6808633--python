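"""Scoring of concept predictions and the sweep experiments.

Two measures are reported for every run:

* **semantic score** — the mean, over mentions, of the Wang et al. DAG
  semantic similarity between the top-1 predicted concept and the
  reference concept (max over references when a mention has several).
  The measure rewards near-misses: predicting a parent of the reference
  scores high, predicting an unrelated concept scores low.
* **strict score** — plain top-1 accuracy: a mention contributes 1 only
  when the predicted concept *is* a reference concept.

The strict score can never exceed the semantic score, because Wang
similarity is 1 exactly on identical concepts and positive otherwise.
Mentions that could not be projected (fully out-of-vocabulary surface
forms) count as 0 under both measures rather than being dropped.

Wang similarity of concepts A and B with contribution factor ``f``:
``S_A(A) = 1``; for any other ancestor ``t`` of A,
``S_A(t) = max over children t' of t inside A's ancestor DAG of
f * S_A(t')``; the semantic value ``SV(A)`` is the sum of S-values over
A's reflexive ancestor closure ``T_A``; and
``sim(A, B) = sum_{t in T_A & T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .concept_space import ConceptVectorSpace, build_decay_sso, reduce_dimensions
from .ontology import Ontology, ancestors
from .projection import Prediction, fit_projection, predict_concepts
from .term_space import AnnotationPair, WordEmbeddings, term_vector

__all__ = [
    "SimilarityConfig",
    "EvaluationReport",
    "wang_similarity",
    "score_predictions",
    "run_pipeline",
    "sweep_decay",
    "sweep_reduction",
    "DEFAULT_DECAY_GRID",
]

DEFAULT_DECAY_GRID = tuple(round(0.1 * i, 1) for i in range(11))  # 0.0 .. 1.0


@dataclass(frozen=True)
class SimilarityConfig:
    """Configuration of the Wang measure.

    ``contribution_factor`` is the per-edge semantic contribution weight
    (strictly between 0 and 1); 0.65 is a conventional default and is
    recorded in every report so runs stay comparable.
    """

    contribution_factor: float = 0.65

    def __post_init__(self) -> None:
        if not 0.0 < self.contribution_factor < 1.0:
            raise ValueError(
                f"contribution_factor must be in (0, 1), "
                f"got {self.contribution_factor}"
            )


def _s_values(onto: Ontology, a: str, factor: float) -> dict[str, float]:
    """S-values of every ancestor of ``a`` via memoized recursion.

    ``S_A(t)`` looks *down* the ancestor DAG: it is the best decayed path
    from ``t`` back to ``a`` through children that are themselves in
    ``T_A``.
    """
    T = ancestors(onto, a)
    children_in_T: dict[str, list[str]] = {t: [] for t in T}
    for x in T:
        for p in onto.parents.get(x, ()):
            if p in T:
                children_in_T[p].append(x)
    memo: dict[str, float] = {a: 1.0}

    def S(t: str) -> float:
        if t not in memo:
            memo[t] = max(factor * S(ch) for ch in children_in_T[t])
        return memo[t]

    for t in T:
        S(t)
    return memo


def wang_similarity(
    onto: Ontology, a: str, b: str, cfg: SimilarityConfig = SimilarityConfig()
) -> float:
    """Wang et al. semantic similarity in (0, 1]; 1 iff ``a == b``."""
    if a not in onto.concepts:
        raise KeyError(f"unknown concept: {a!r}")
    if b not in onto.concepts:
        raise KeyError(f"unknown concept: {b!r}")
    sa = _s_values(onto, a, cfg.contribution_factor)
    sb = _s_values(onto, b, cfg.contribution_factor)
    shared = set(sa) & set(sb)
    num = sum(sa[t] + sb[t] for t in shared)
    return num / (sum(sa.values()) + sum(sb.values()))


@dataclass
class EvaluationReport:
    """Per-run scores plus per-mention records.

    Each record is ``(mention, predicted or None, references, similarity)``.
    """

    semantic_score: float
    strict_score: float
    n_mentions: int
    n_no_vector: int
    records: list[tuple[str, str | None, frozenset[str], float]]
    meta: dict = field(default_factory=dict)


def score_predictions(
    preds: list[Prediction],
    refs: dict[str, frozenset[str] | set[str]],
    onto: Ontology,
    cfg: SimilarityConfig = SimilarityConfig(),
) -> EvaluationReport:
    """Score top-1 predictions against reference concept sets.

    Multi-reference mentions score the max similarity over references; a
    ``no_vector`` prediction contributes 0 to both measures.
    """
    records = []
    sims, stricts = [], []
    n_no_vector = 0
    for pred in preds:
        if pred.mention not in refs:
            raise KeyError(f"no reference for mention {pred.mention!r}")
        ref = frozenset(refs[pred.mention])
        if not ref:
            raise ValueError(f"empty reference set for mention {pred.mention!r}")
        if pred.status == "no_vector" or not pred.ranking:
            n_no_vector += 1
            records.append((pred.mention, None, ref, 0.0))
            sims.append(0.0)
            stricts.append(0.0)
            continue
        top = pred.ranking[0][0]
        sim = max(wang_similarity(onto, top, r, cfg) for r in ref)
        records.append((pred.mention, top, ref, sim))
        sims.append(sim)
        stricts.append(1.0 if top in ref else 0.0)
    n = len(preds)
    return EvaluationReport(
        semantic_score=float(np.mean(sims)) if n else 0.0,
        strict_score=float(np.mean(stricts)) if n else 0.0,
        n_mentions=n,
        n_no_vector=n_no_vector,
        records=records,
        meta={"contribution_factor": cfg.contribution_factor},
    )


def _vectorize_pairs(
    emb: WordEmbeddings, pairs: list[AnnotationPair]
) -> list[tuple[np.ndarray, str]]:
    out = []
    for p in pairs:
        v, cov = term_vector(emb, list(p.tokens))
        if cov > 0:
            out.append((v, p.concept_id))
    return out


def run_pipeline(
    onto: Ontology,
    sso: ConceptVectorSpace,
    emb: WordEmbeddings,
    train_pairs: list[AnnotationPair],
    eval_pairs: list[AnnotationPair],
    loss: str = "least_squares",
    cfg: SimilarityConfig = SimilarityConfig(),
    seed: int = 0,
) -> EvaluationReport:
    """Train a projection on ``train_pairs`` and score it on ``eval_pairs``.

    Each evaluation pair is treated as one mention occurrence; its key in
    the reference mapping is made unique by position so repeated surface
    forms do not collide.
    """
    vec_pairs = _vectorize_pairs(emb, train_pairs)
    proj = fit_projection(vec_pairs, sso, loss=loss, seed=seed)
    preds: list[Prediction] = []
    refs: dict[str, frozenset[str]] = {}
    for i, p in enumerate(eval_pairs):
        key = f"{i}:{p.surface}"
        x, _cov = term_vector(emb, list(p.tokens))
        pred = predict_concepts(proj, sso, x, k=1, mention=key)
        preds.append(pred)
        refs.setdefault(key, frozenset())
        refs[key] = refs[key] | {p.concept_id}
    return score_predictions(preds, refs, onto, cfg)


def sweep_decay(
    onto: Ontology,
    train_pairs: list[AnnotationPair],
    eval_pairs: list[AnnotationPair],
    emb: WordEmbeddings,
    grid=DEFAULT_DECAY_GRID,
    cfg: SimilarityConfig = SimilarityConfig(),
    loss: str = "least_squares",
    seed: int = 0,
) -> list[dict]:
    """Run the full pipeline for each decay factor in ``grid``.

    The default grid is 0.0 to 1.0 in steps of 0.1 (11 rows); row fields
    are ``w``, ``semantic_score``, ``strict_score``.
    """
    rows = []
    for w in grid:
        sso = build_decay_sso(onto, w)
        rep = run_pipeline(
            onto, sso, emb, train_pairs, eval_pairs, loss=loss, cfg=cfg, seed=seed
        )
        rows.append(
            {
                "w": w,
                "semantic_score": rep.semantic_score,
                "strict_score": rep.strict_score,
            }
        )
    return rows


def sweep_reduction(
    onto: Ontology,
    train_pairs: list[AnnotationPair],
    eval_pairs: list[AnnotationPair],
    emb: WordEmbeddings,
    method: str = "svd",
    fractions=(0.0, 0.3, 0.6, 0.9),
    base_w: float = 1.0,
    cfg: SimilarityConfig = SimilarityConfig(),
    loss: str = "least_squares",
    seed: int = 0,
) -> list[dict]:
    """Score the pipeline at several SSO reduction fractions.

    Fraction ``f`` keeps ``ceil((1 - f) * dim)`` dimensions of the decay
    SSO built at ``base_w``; fraction 0 with svd is a full-rank orthogonal
    change of basis and reproduces the unreduced scores.
    """
    base = build_decay_sso(onto, base_w)
    rows = []
    for f in fractions:
        if not 0.0 <= f < 1.0:
            raise ValueError(f"reduction fraction must be in [0, 1), got {f}")
        target = math.ceil((1.0 - f) * base.dimension)
        sso = reduce_dimensions(base, method, target, seed=seed)
        rep = run_pipeline(
            onto, sso, emb, train_pairs, eval_pairs, loss=loss, cfg=cfg, seed=seed
        )
        rows.append(
            {
                "fraction": f,
                "target_dim": target,
                "semantic_score": rep.semantic_score,
                "strict_score": rep.strict_score,
            }
        )
    return rows
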