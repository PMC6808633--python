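"""Linear projection from the term space (SSC) into the concept space
(SSO), and cosine nearest-neighbor concept prediction.

Training seeks a linear map A (plus optional bias b) such that for each
training pair (x, c) the projected vector A x + b points in the direction
of the concept vector y_c — i.e. the mean cosine similarity between
projections and targets over the training set is maximal.  Two fitting
routes are provided:

* ``least_squares`` — closed-form multivariate least squares against the
  (by default unit-normalized) target rows.  Deterministic, no tuning;
  with normalized targets it is the classical tractable surrogate for the
  cosine objective and is the default.
* ``cosine`` — direct full-batch gradient ascent on the mean cosine,
  initialized from a small random matrix with a fixed seed and run for a
  fixed iteration budget (Adam).  Slower, but optimizes the stated
  objective itself.

Prediction ranks all concepts by cosine between the projected query and
each SSO row; ties break lexicographically on the concept identifier, and
an all-zero projection (e.g. a fully out-of-vocabulary mention) yields an
explicit ``no_vector`` status instead of a ranking computed from noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .concept_space import ConceptVectorSpace

__all__ = [
    "TrainedProjection",
    "Prediction",
    "fit_projection",
    "project",
    "predict_concepts",
    "save_projection",
    "load_projection",
]


@dataclass
class TrainedProjection:
    """Linear map SSC -> SSO with training metadata.

    ``map_matrix`` has shape (SSO dim, SSC dim); ``bias`` has SSO dim.
    """

    map_matrix: np.ndarray
    bias: np.ndarray
    training_meta: dict = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        return int(self.map_matrix.shape[1])

    @property
    def output_dim(self) -> int:
        return int(self.map_matrix.shape[0])


@dataclass
class Prediction:
    """Ranked concepts for one mention.

    ``ranking`` is a list of (concept identifier, cosine score), sorted by
    non-increasing score with lexicographic tie-breaking.  ``status`` is
    ``"no_vector"`` (with empty ranking) when the mention could not be
    projected to a nonzero vector.
    """

    mention: str
    ranking: list[tuple[str, float]]
    status: str = "ok"  # ok | no_vector

    @property
    def top(self) -> str | None:
        return self.ranking[0][0] if self.ranking else None


def _unit_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    return M / np.where(norms == 0, 1.0, norms)


def fit_projection(
    pairs,
    sso: ConceptVectorSpace,
    loss: str = "least_squares",
    normalize_targets: bool = True,
    use_bias: bool = True,
    seed: int = 0,
    cosine_iters: int = 500,
    cosine_lr: float = 0.05,
) -> TrainedProjection:
    """Fit the linear map from (term vector, concept) pairs.

    Pairs whose term vector is all-zero (unpredictable OOV mentions) are
    rejected with a warning and counted in ``training_meta``.
    """
    if loss not in ("least_squares", "cosine"):
        raise ValueError(f"unknown loss: {loss!r}")
    xs, ys = [], []
    n_rejected = 0
    for x, concept in pairs:
        if concept not in sso.index:
            raise KeyError(f"training concept missing from SSO: {concept!r}")
        x = np.asarray(x, dtype=float)
        if not np.any(x):
            n_rejected += 1
            continue
        xs.append(x)
        ys.append(sso.vector(concept))
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} all-zero term vectors from training",
            stacklevel=2,
        )
    if not xs:
        raise ValueError("no usable training pairs (all rejected or empty)")
    X = np.vstack(xs)
    Y = np.vstack(ys)
    if normalize_targets:
        Y = _unit_rows(Y)

    meta = {
        "loss": loss,
        "n_pairs": len(xs),
        "n_rejected": n_rejected,
        "normalize_targets": normalize_targets,
        "use_bias": use_bias,
        "seed": seed,
    }
    if loss == "least_squares":
        A, b = _fit_least_squares(X, Y, use_bias)
    else:
        A, b = _fit_cosine(X, Y, use_bias, seed, cosine_iters, cosine_lr)
    proj = TrainedProjection(A, b, meta)
    P = project_many(proj, X)
    meta["final_mean_cosine"] = float(
        np.mean(np.sum(_unit_rows(P) * _unit_rows(Y), axis=1))
    )
    return proj


def _fit_least_squares(
    X: np.ndarray, Y: np.ndarray, use_bias: bool
) -> tuple[np.ndarray, np.ndarray]:
    if use_bias:
        Xb = np.hstack([X, np.ones((X.shape[0], 1))])
    else:
        Xb = X
    W, *_ = np.linalg.lstsq(Xb, Y, rcond=None)
    if use_bias:
        return W[:-1].T, W[-1].copy()
    return W.T, np.zeros(Y.shape[1])


def _fit_cosine(
    X: np.ndarray,
    Y: np.ndarray,
    use_bias: bool,
    seed: int,
    iters: int,
    lr: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Full-batch Adam ascent on mean cosine(A x + b, y)."""
    rng = np.random.default_rng(seed)
    n, d_in = X.shape
    d_out = Y.shape[1]
    A = rng.normal(scale=0.1, size=(d_out, d_in))
    b = np.zeros(d_out)
    Yh = _unit_rows(Y)
    mA = np.zeros_like(A)
    vA = np.zeros_like(A)
    mb = np.zeros_like(b)
    vb = np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for t in range(1, iters + 1):
        P = X @ A.T + b  # (n, d_out)
        norms = np.linalg.norm(P, axis=1, keepdims=True)
        norms = np.where(norms == 0, 1.0, norms)
        Ph = P / norms
        cos = np.sum(Ph * Yh, axis=1, keepdims=True)
        # d cos / d P = (y_hat - cos * p_hat) / |p|
        G = (Yh - cos * Ph) / norms / n
        gA = G.T @ X
        gb = G.sum(axis=0)
        for g, m, v, param in ((gA, mA, vA, A), (gb, mb, vb, b)):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mh = m / (1 - beta1**t)
            vh = v / (1 - beta2**t)
            param += lr * mh / (np.sqrt(vh) + eps)  # ascent
        if not use_bias:
            b[:] = 0.0
    return A, b


def project(p: TrainedProjection, x: np.ndarray) -> np.ndarray:
    """Apply the trained map: ``map_matrix @ x + bias``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != p.input_dim:
        raise ValueError(
            f"term vector has dimension {x.shape[-1]}, projection was "
            f"trained on dimension {p.input_dim}"
        )
    return p.map_matrix @ x + p.bias


def project_many(p: TrainedProjection, X: np.ndarray) -> np.ndarray:
    return X @ p.map_matrix.T + p.bias


def predict_concepts(
    p: TrainedProjection,
    sso: ConceptVectorSpace,
    x: np.ndarray,
    k: int = 1,
    mention: str = "",
) -> Prediction:
    """Rank concepts by cosine similarity to the projected term vector."""
    if not 1 <= k <= len(sso.index):
        raise ValueError(f"k must be in [1, {len(sso.index)}], got {k}")
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        return Prediction(mention=mention, ranking=[], status="no_vector")
    v = project(p, x)
    vnorm = np.linalg.norm(v)
    if vnorm == 0:
        return Prediction(mention=mention, ranking=[], status="no_vector")
    M = sso.matrix
    norms = np.linalg.norm(M, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    scores = (M @ v) / (safe * vnorm)
    scores[norms == 0] = -np.inf
    concepts = sso.concepts
    order = sorted(range(len(concepts)), key=lambda i: (-scores[i], concepts[i]))
    ranking = [(concepts[i], float(scores[i])) for i in order[:k]]
    return Prediction(mention=mention, ranking=ranking, status="ok")


def save_projection(p: TrainedProjection, path) -> None:
    """Write the map as a TSV matrix; bias and meta go to a JSON sidecar."""
    path = str(path)
    with open(path, "w", encoding="utf-8") as fh:
        for row in p.map_matrix:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    sidecar = dict(p.training_meta)
    sidecar["bias"] = [float(v) for v in p.bias]
    with open(path + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def load_projection(path) -> TrainedProjection:
    path = str(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            rows.append([float(v) for v in line.rstrip("\n").split("\t")])
    M = np.array(rows)
    with open(path + ".meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    bias = np.array(meta.pop("bias", np.zeros(M.shape[0]).tolist()))
    return TrainedProjection(M, bias, meta)
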