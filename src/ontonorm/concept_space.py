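"""Concept vector spaces (SSO): ancestry/decay vectors, graph embeddings,
and dimensionality-reduced variants.

The central representation maps each ontology concept to one row of a real
matrix.  The ancestry family assigns the row of concept ``c`` the value
``w**d`` at the dimension of each ancestor ``a``, where ``d`` is the
minimum is-a edge distance from ``c`` to ``a`` and ``w`` in [0, 1] is the
decay factor; ``0**0 == 1`` by convention so the self entry is always 1.
The two limits are classical representations: ``w == 1`` is the binary
ancestry encoding (1 on the concept and every ancestor) and ``w == 0`` is
one-hot.  Intermediate ``w`` down-weights distant ancestors, which
counteracts the tendency of ancestry-trained projections to predict overly
general concepts.

Alternatively, concepts can be embedded with node2vec-style biased random
walks over the (undirected) is-a graph, which yields low-dimensional
vectors independent of ontology size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .ontology import Ontology, ancestor_distances
from .word2vec import train_embeddings

__all__ = [
    "ConceptVectorSpace",
    "GraphEmbedConfig",
    "build_decay_sso",
    "build_ancestry_sso",
    "build_onehot_sso",
    "build_node2vec_sso",
    "reduce_dimensions",
    "save_space",
    "load_space",
]


@dataclass
class ConceptVectorSpace:
    """A matrix of one vector per concept plus construction metadata.

    ``index`` is a bijection concept identifier -> row number; rows follow
    the ontology's fixed lexicographic concept order at construction.
    """

    matrix: np.ndarray
    index: dict[str, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.index) != self.matrix.shape[0]:
            raise ValueError(
                f"index has {len(self.index)} concepts for "
                f"{self.matrix.shape[0]} matrix rows"
            )
        if sorted(self.index.values()) != list(range(self.matrix.shape[0])):
            raise ValueError("index is not a bijection onto matrix rows")

    @property
    def dimension(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def concepts(self) -> list[str]:
        return sorted(self.index, key=self.index.__getitem__)

    def vector(self, concept: str) -> np.ndarray:
        return self.matrix[self.index[concept]]


@dataclass(frozen=True)
class GraphEmbedConfig:
    """node2vec hyperparameters.

    ``p`` (return) and ``q`` (in-out) bias the second-order walk exactly as
    in the original method: the unnormalized probability of stepping from
    the current node to neighbor ``x`` is ``1/p`` if ``x`` is the previous
    node, ``1`` if ``x`` neighbors the previous node, else ``1/q``.
    """

    dimension: int = 64
    walk_length: int = 10
    walks_per_node: int = 20
    p: float = 1.0
    q: float = 1.0
    window: int = 5
    epochs: int = 3
    seed: int = 0
    include_extra_edges: bool = False

    def __post_init__(self) -> None:
        if self.dimension < 1 or self.walk_length < 1 or self.walks_per_node < 1:
            raise ValueError("dimension, walk_length and walks_per_node must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


def build_decay_sso(onto: Ontology, w: float) -> ConceptVectorSpace:
    """Decay-weighted ancestry space: entry (c, a) = w**d(c, a).

    ``w`` must lie in [0, 1].  ``w == 1`` gives the binary ancestry matrix,
    ``w == 0`` the one-hot (identity-pattern) matrix.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"decay factor must be in [0, 1], got {w}")
    order = onto.order
    index = {c: i for i, c in enumerate(order)}
    n = len(order)
    M = np.zeros((n, n))
    for c, i in index.items():
        for a, d in ancestor_distances(onto, c).items():
            M[i, index[a]] = 1.0 if d == 0 else w**d  # 0**0 := 1
    name = {0.0: "onehot", 1.0: "ancestry"}.get(w, "decay")
    return ConceptVectorSpace(M, index, {"method": name, "decay": w})


def build_ancestry_sso(onto: Ontology) -> ConceptVectorSpace:
    """Binary ancestry vectors (the w=1 decay limit)."""
    return build_decay_sso(onto, 1.0)


def build_onehot_sso(onto: Ontology) -> ConceptVectorSpace:
    """One-hot vectors (the w=0 decay limit)."""
    return build_decay_sso(onto, 0.0)


def _adjacency(onto: Ontology, include_extra: bool) -> dict[str, list[str]]:
    adj: dict[str, set[str]] = {c: set() for c in onto.concepts}
    for c, ps in onto.parents.items():
        for p in ps:
            adj[c].add(p)
            adj[p].add(c)
    if include_extra:
        for s, _rel, t in onto.extra_edges:
            adj[s].add(t)
            adj[t].add(s)
    return {c: sorted(ns) for c, ns in adj.items()}


def _biased_walk(
    adj: dict[str, list[str]],
    start: str,
    length: int,
    p: float,
    q: float,
    rng: np.random.Generator,
) -> list[str]:
    walk = [start]
    if not adj[start]:
        return walk  # isolated node: zero-length walk permitted
    while len(walk) < length:
        cur = walk[-1]
        nbrs = adj[cur]
        if not nbrs:
            break
        if len(walk) == 1:
            walk.append(nbrs[int(rng.integers(len(nbrs)))])
            continue
        prev = walk[-2]
        prev_nbrs = set(adj[prev])
        weights = np.array(
            [
                1.0 / p if x == prev else (1.0 if x in prev_nbrs else 1.0 / q)
                for x in nbrs
            ]
        )
        weights /= weights.sum()
        walk.append(nbrs[int(rng.choice(len(nbrs), p=weights))])
    return walk


def build_node2vec_sso(
    onto: Ontology, cfg: GraphEmbedConfig = GraphEmbedConfig()
) -> ConceptVectorSpace:
    """Embed concepts with biased random walks + skip-gram.

    The is-a graph is treated as undirected with unit weights; non-is-a
    relationships are included when ``cfg.include_extra_edges`` is set.
    Fixed seed (single worker) gives reproducible output.
    """
    adj = _adjacency(onto, cfg.include_extra_edges)
    rng = np.random.default_rng(cfg.seed)
    nodes = onto.order
    walks: list[list[str]] = []
    for _ in range(cfg.walks_per_node):
        for node in nodes:
            walks.append(_biased_walk(adj, node, cfg.walk_length, cfg.p, cfg.q, rng))
    model = train_embeddings(
        walks,
        dimension=cfg.dimension,
        mode="skipgram",
        window=cfg.window,
        min_count=1,
        epochs=cfg.epochs,
        seed=cfg.seed,
    )
    index = {c: i for i, c in enumerate(nodes)}
    M = np.vstack([model.vectors[model.vocab[c]] for c in nodes])
    return ConceptVectorSpace(
        M, index, {"method": "node2vec", **asdict(cfg)}
    )


def reduce_dimensions(
    sso: ConceptVectorSpace, method: str, target_dim: int, seed: int = 0
) -> ConceptVectorSpace:
    """Reduce an SSO to ``target_dim`` columns with pca, mds or svd.

    ``pca`` projects onto centered principal components, ``svd`` onto
    uncentered right singular vectors (an orthogonal transform: at full
    rank it preserves pairwise cosines exactly), and ``mds`` runs metric
    multidimensional scaling on Euclidean row distances with a fixed seed.
    ``tsne`` is refused outright: it does not scale past a handful of output
    dimensions and is unsuitable for producing concept spaces.
    """
    if method == "tsne":
        raise ValueError(
            "t-SNE is not supported as an SSO reduction: it is designed for "
            "2D/3D visualization and does not scale to the output "
            "dimensionalities a concept space needs; use pca, mds or svd"
        )
    if method not in ("pca", "mds", "svd"):
        raise ValueError(f"unknown reduction method: {method!r}")
    if not 1 <= target_dim <= sso.dimension:
        raise ValueError(
            f"target_dim must be in [1, {sso.dimension}], got {target_dim}"
        )
    X = sso.matrix
    if method == "svd":
        # Uncentered truncated SVD; rows re-expressed as U @ diag(S).
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        R = U[:, :target_dim] * S[:target_dim]
    elif method == "pca":
        from sklearn.decomposition import PCA

        R = PCA(n_components=target_dim, random_state=seed).fit_transform(X)
    else:
        import warnings

        from sklearn.manifold import MDS

        with warnings.catch_warnings():
            # a square SSO (ancestry matrix) is genuinely samples x features;
            # sklearn warns in case the caller meant a precomputed matrix
            warnings.filterwarnings("ignore", message=".*square matrix.*")
            R = MDS(
                n_components=target_dim,
                metric="euclidean",
                init="random",
                random_state=seed,
                normalized_stress=False,
            ).fit_transform(X)
    meta = dict(sso.meta)
    meta.update(
        method="reduced",
        base_method=sso.meta.get("method"),
        reduction=method,
        target_dim=target_dim,
        reduction_fraction=1.0 - target_dim / sso.dimension,
        seed=seed,
    )
    return ConceptVectorSpace(R, dict(sso.index), meta)


def save_space(sso: ConceptVectorSpace, path) -> None:
    """Write concept vectors as TSV plus a JSON meta sidecar."""
    path = str(path)
    with open(path, "w", encoding="utf-8") as fh:
        for c in sso.concepts:
            row = "\t".join(repr(float(v)) for v in sso.vector(c))
            fh.write(f"{c}\t{row}\n")
    with open(path + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(sso.meta, fh, indent=2, default=str)


def load_space(path) -> ConceptVectorSpace:
    path = str(path)
    concepts, rows = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            concepts.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    try:
        with open(path + ".meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    index = {c: i for i, c in enumerate(concepts)}
    return ConceptVectorSpace(np.array(rows), index, meta)
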