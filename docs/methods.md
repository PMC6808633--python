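# Methods

## The model

`ontonorm` normalizes textual entity mentions to concepts of an ontology by
relating two vector spaces:

* **SSC** (semantic space of the corpus): each word gets a dense vector from
  distributional training (skip-gram, CBOW, or a subword variant); a
  multiword term's vector is the unweighted mean of its token vectors.
* **SSO** (semantic space of the ontology): each concept `c` gets a vector
  derived from its position in the is-a hierarchy. In the decay family the
  entry at the dimension of ancestor `a` is `w^d(c,a)`, where `d` is the
  minimum number of is-a edges from `c` to `a` (0 for the concept itself, 1
  for a direct parent) and `w ∈ [0,1]` is the decay factor. With `0^0 := 1`
  the self-entry is always 1; `w = 1` recovers the classical binary
  "ancestry" encoding and `w = 0` the one-hot encoding. Alternatively,
  concepts are embedded with node2vec-style biased random walks over the
  undirected is-a graph fed to a skip-gram objective, which decouples the
  vector dimension from ontology size.

A linear map `A` (optionally affine, `A x + b`) is fitted so that projected
term vectors point toward their concepts' vectors, i.e. the mean cosine
similarity over training pairs `(x, y_c)` is maximal. Prediction for a new
mention ranks all concepts by cosine between `A x + b` and each SSO row.
Training pairs come from corpus annotations (supervised), from concept
labels and synonyms alone (unsupervised), or both.

The premise is that distributional similarity between terms mirrors
ontological proximity between their concepts; a *linear* map suffices to
carry one geometry into the other when that premise roughly holds. Ancestor
sharing in the SSO makes near-miss predictions land close to the reference
in the hierarchy; the decay factor controls how strongly ancestors attract
the fit, and hence how much the system generalizes upward (small `w` =
sharper, more literal predictions; large `w` = smoother, more general ones).

## Fitting

Two losses are available:

* `least_squares` (default): closed-form multivariate least squares of the
  (unit-normalized, by default) target rows on the term vectors, with bias.
  Deterministic and tuning-free; with normalized targets it is the standard
  tractable surrogate for the cosine objective.
* `cosine`: full-batch Adam ascent on the mean cosine itself (default 500
  iterations, learning rate 0.05, fixed seed for the initialization).
  On planted linear instances it reaches mean training cosine ≥ 0.99,
  verified against the least-squares solution.

Targets are unit-normalized by default (aligning the surrogate with the
cosine objective); the bias is on by default (it improves the fit on
uncentered embeddings). Both are flags. Note that with a bias the map is
affine, so cosine ranking is invariant to positive scaling of the query
only in the bias-free configuration; the discrepancy is tiny in practice
but the exact invariance is only claimed (and tested) for the linear map.

All-zero term vectors (every token out of vocabulary) are *rejected* from
training with a warning count, and at prediction time yield an explicit
`no_vector` status rather than a ranking computed from noise. Ties in the
cosine ranking break lexicographically on the concept identifier.

## Evaluation

Two measures per run, with the strict one never above the semantic one:

* **semantic score**: mean Wang et al. DAG similarity between the top-1
  prediction and the reference (max over references when several).
  `S_A(A) = 1`; for an ancestor `t` of `A`, `S_A(t)` is the per-edge
  contribution factor times the best child S-value inside A's ancestor DAG;
  `sim(A,B) = Σ_{t ∈ T_A∩T_B}(S_A(t)+S_B(t)) / (SV(A)+SV(B))`. For a
  contribution factor in (0,1) the recursion collapses to
  `factor^min_edge_distance`, which is how the implementation computes it;
  tests check it against an exhaustive path-enumeration oracle. The
  contribution factor defaults to 0.65 (a conventional choice — the
  measure's definition does not fix it) and is recorded in every report.
* **strict score**: top-1 exact-match accuracy.

`no_vector` mentions count as 0 under both measures instead of being
dropped; dropping them would silently inflate scores on OOV-heavy corpora.

The sweep experiments re-run the full build-fit-predict-score pipeline per
grid point: the decay sweep over `w = 0.0 … 1.0` in steps of 0.1 (11 rows),
and the reduction sweep over SSO dimensionality-reduction fractions with
PCA (centered principal components), metric MDS (Euclidean dissimilarities,
fixed seed), or uncentered truncated SVD. A full-rank SVD is an orthogonal
change of basis and reproduces unreduced scores exactly; t-SNE is refused
with an explicit error since it only targets 2-3 output dimensions and
cannot serve as a concept-space reduction.

## Word embeddings

The trainer is a compact numpy implementation of the word2vec family with
negative sampling (5 noise words, unigram^0.75 noise distribution, linearly
decayed learning rate from 0.025, dynamic window). The subword mode follows
the fastText construction: a word is a bag of character 3-6-grams with
boundary markers, hashed into 2^16 buckets (FNV-1a); a word's input vector
is the mean of its own vector and its n-gram vectors, so an unseen word
still composes a finite vector from n-grams alone, whereas skip-gram/CBOW
return an explicit OOV signal. Everything runs single-worker with a seeded
generator, so embeddings are byte-identical across runs.

These defaults are configuration, not fidelity claims: at desk scale (a few
hundred sentences, dimension 20) they produce embeddings good enough for
the planted synthetic benchmark; none of the hyperparameters were chosen to
match any external system.

## node2vec configuration

Defaults: dimension 64, walk length 10, 20 walks per node, p = q = 1,
window 5, 3 training epochs. Walks treat is-a edges as undirected with unit
weight; non-subsumption relationships (e.g. `sameAs`) can be included with
a flag. An isolated concept yields a single-node walk and still receives a
(randomly initialized, untrained) vector. On a 30-concept path graph,
adjacent concepts embed measurably closer than concepts ten or more edges
apart for the large majority of seeds — the locality property the walks are
meant to induce.

## Synthetic data

The generators stand in for a real normalization corpus and ontology at
desk scale, and define the package's study conditions:

* **Ontology**: `n` concepts (default 50), concept `i > 0` draws 1 to
  `max_parents` (default 2) parents uniformly from earlier concepts —
  construction order is a topological order, so acyclicity is guaranteed.
* **Lexicon/corpus**: 3 pseudo-words per concept; 12 sentences of 8 tokens
  per concept, each token drawn from the concept's own vocabulary with
  probability 0.7 and from a parent's with probability 0.3. The mixing
  plants the central premise (distributional similarity ↔ ontological
  proximity) into the corpus by construction.
* **Annotations**: 200 mentions of 1-2 concept words; the last 30% are the
  held-out split, and 10% of the held-out mentions use a reserved word that
  never occurs in the corpus, exercising the OOV path end to end.
* **Planted instances**: `x_c = G y_c + ε` with `G` i.i.d. normal scaled by
  `1/√dim` (well conditioned with overwhelming probability) and ε Gaussian.

What passing tests on this data show: the machinery recovers planted
structure, the decay limits behave as derived, and the pipeline beats a
1,000-draw Monte-Carlo random-assignment baseline. What they do not show:
performance on real biomedical text, which has ambiguity, morphology and
annotation noise the generator deliberately omits.

Noise-robustness checks evaluate *out of sample* (fresh noise draws through
the same planted map): with 50 pairs and a 21-parameter-per-dimension
affine fit, in-sample accuracy stays high even on pure noise through the
hat matrix, so only held-out draws measure recovery. The planted-recovery
benchmark uses one-hot concept targets: with mutually orthogonal targets
rank-1 recovery at zero noise is exact, whereas binary ancestry targets of
parent and child overlap so strongly that rank-1 confusions occur even
noise-free (about 0.8 accuracy at 50 concepts) — an intrinsic property of
that encoding, not a fitting failure.

## Numerical and design choices

* Concept dimension order is lexicographic in the identifier, fixed at
  ontology construction — matrices are reproducible across runs.
* `d(c, a)` on a DAG is the minimum edge count over directed paths (each
  ancestor gets its maximal weight `w^d`); reduces to path length on trees.
* SSO rows are not normalized at construction; normalization happens at
  projection-training time. Construction stays faithful to the `w^d`
  values, and the decay-limit identities hold exactly.
* OBO parsing is line-based and reports the offending line on malformed
  input; obsolete terms are skipped; a cycle in is_a fails validation with
  one explicit cycle listed. The writer emits the same dialect, and
  read-write round-trips are exact.
* Problem sizes in tests and in the acceptance script (50-concept
  ontologies, dimension-20 embeddings, 200 mentions, 5 seeds, 1,000
  Monte-Carlo draws) are the package's chosen desk-scale study conditions:
  large enough for the properties to be non-trivial, small enough to keep
  any run interactive.

## Known limitations

* The linear projection cannot separate concepts whose term vectors are
  distributionally confounded; it inherits every bias of the embeddings.
* Ancestry-style SSO dimensionality grows with ontology size (the
  motivation for the reduction and graph-embedding variants); the decay
  construction is dense and quadratic in concepts, fine for thousands of
  concepts, not for millions.
* The subword trainer hashes n-grams into a fixed table; collisions are
  harmless at desk scale but untested at real-vocabulary scale.
* Multi-reference evaluation uses max-over-references for the top-1
  prediction — the most permissive deterministic rule; official shared-task
  scorers may pair differently.
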