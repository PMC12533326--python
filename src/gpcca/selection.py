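"""Latent-dimension selection by consensus over repeated EM fits.

For each candidate latent dimension the model is fitted from ``B`` random
initializations; each embedding is clustered by Louvain community detection
on a shared-nearest-neighbor graph; the agreement of the ``B`` partitions is
summarized by a consensus matrix ``C`` (pairwise co-clustering frequency)
and scored by ``H = sum_{i<j} C_ij log2 C_ij``, which is 0 exactly when all
runs agree and more negative the less stable the clustering is.  The
candidate with the largest score wins; within the winning candidate the
initialization whose connectivity matrix is closest to the consensus matrix
(smallest RMSE over pairs) is selected.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, replace

import igraph
import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .data import MultiModalDataset
from .model import FitConfig, fit

__all__ = [
    "ConsensusState",
    "cluster_embedding",
    "connectivity_matrix",
    "consensus_matrix",
    "consensus_score",
    "consensus_rmse",
    "select_best_initialization",
    "select_latent_dimension",
]

#: Louvain resolution used throughout unless overridden.
DEFAULT_RESOLUTION = 0.8
#: Neighbors in the shared-nearest-neighbor graph.
DEFAULT_NEIGHBORS = 15
#: SNN edges with Jaccard weight below this are pruned (Seurat convention).
SNN_PRUNE = 1.0 / 15.0


@dataclass
class ConsensusState:
    """Clustering stability summary for one candidate latent dimension."""

    candidate_d: int
    labels: np.ndarray          # (n, B) integer cluster assignments
    consensus: np.ndarray       # (n, n) co-clustering frequency
    score: float                # consensus score, <= 0
    connectivity: np.ndarray    # (B, n, n) binary co-membership per init
    rmse: np.ndarray            # (B,) distance of each init to the consensus
    models: list                # the B fitted models
    fit_seeds: np.ndarray
    cluster_seeds: np.ndarray

    @property
    def B(self) -> int:
        return self.labels.shape[1]

    @property
    def best_init(self) -> int:
        return select_best_initialization(self)


def _snn_graph(points: np.ndarray, n_neighbors: int) -> igraph.Graph:
    """Weighted SNN graph over rows of ``points``.

    Each sample is linked to its ``n_neighbors`` nearest neighbors
    (Euclidean); edge weights are the Jaccard overlap of the two samples'
    neighbor sets (self included), pruned below :data:`SNN_PRUNE`.
    """
    n = points.shape[0]
    k = n_neighbors
    if k > n - 1:
        warnings.warn(
            f"n_neighbors={k} exceeds n-1={n - 1}; clamping", RuntimeWarning
        )
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k).fit(points)
    ind = nn.kneighbors(return_distance=False)  # (n, k), self excluded
    rows = np.repeat(np.arange(n), k)
    adj = sparse.csr_matrix(
        (np.ones(n * k + n), (np.concatenate([rows, np.arange(n)]),
                              np.concatenate([ind.ravel(), np.arange(n)]))),
        shape=(n, n),
    )
    shared = (adj @ adj.T).tocoo()              # |N(i) & N(j)|
    keep = shared.row < shared.col
    r, c, s = shared.row[keep], shared.col[keep], shared.data[keep]
    jac = s / (2.0 * (k + 1) - s)
    strong = jac >= SNN_PRUNE
    edges = np.column_stack([r[strong], c[strong]])
    g = igraph.Graph(n=n, edges=edges.tolist())
    g.es["weight"] = jac[strong].tolist()
    return g


def cluster_embedding(
    embedding: np.ndarray,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
    n_neighbors: int = DEFAULT_NEIGHBORS,
) -> np.ndarray:
    """Louvain community labels for the columns of a d x n embedding.

    Modularity optimization runs at the given resolution on the SNN graph;
    the label values are arbitrary but the partition is deterministic given
    the seed.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2:
        raise ValueError("embedding must be a d x n matrix")
    n = embedding.shape[1]
    if n < 2:
        raise ValueError("need at least two samples to cluster")
    g = _snn_graph(embedding.T, n_neighbors)
    igraph.set_random_number_generator(random.Random(int(seed)))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    igraph.set_random_number_generator(random)
    return np.asarray(part.membership, dtype=int)


def connectivity_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary co-membership matrix of one partition (unit diagonal)."""
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_matrix(labels: np.ndarray) -> np.ndarray:
    """Pairwise co-clustering frequency over the columns of an n x B label
    matrix; symmetric with unit diagonal."""
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    n, B = labels.shape
    if B < 1:
        raise ValueError("need at least one clustering")
    C = np.zeros((n, n))
    for b in range(B):
        C += connectivity_matrix(labels[:, b])
    return C / B


def consensus_score(C: np.ndarray) -> float:
    """``sum_{i<j} C_ij log2 C_ij`` with the convention ``0 log 0 = 0``.

    Always <= 0, and 0 exactly when every entry is 0 or 1 (perfectly stable
    clusterings).
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus matrix must be square")
    if (C < 0).any() or (C > 1).any():
        raise ValueError("consensus entries must lie in [0, 1]")
    iu = np.triu_indices(C.shape[0], k=1)
    vals = C[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(vals > 0, vals * np.log2(np.where(vals > 0, vals, 1.0)), 0.0)
    return float(terms.sum())


def consensus_rmse(connectivity: np.ndarray, consensus: np.ndarray) -> float:
    """Root mean squared difference between one partition's connectivity
    matrix and the consensus matrix, over unordered pairs i < j."""
    n = consensus.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = connectivity[iu] - consensus[iu]
    return float(np.sqrt(2.0 / (n * (n - 1)) * np.sum(diff**2)))


def select_best_initialization(state: ConsensusState) -> int:
    """Index of the initialization closest to the consensus (smallest RMSE;
    ties broken by lowest index)."""
    return int(np.argmin(state.rmse))


def _derive_seeds(master_seed: int, n_candidates: int, B: int):
    ss = np.random.SeedSequence(master_seed)
    state = ss.generate_state(2 * n_candidates * B, dtype=np.uint32)
    state = (state % np.uint32(2**31)).astype(np.int64)
    half = n_candidates * B
    return (state[:half].reshape(n_candidates, B),
            state[half:].reshape(n_candidates, B))


def select_latent_dimension(
    dataset: MultiModalDataset,
    candidates,
    B: int,
    config: FitConfig,
    resolution: float = DEFAULT_RESOLUTION,
    n_neighbors: int = DEFAULT_NEIGHBORS,
):
    """Consensus selection of the latent dimension.

    Fits ``B`` models per candidate (seeds derived deterministically from
    ``config.seed``), clusters every embedding, and scores the stability of
    each candidate.  Returns ``(d_star, states)`` where ``states`` maps each
    candidate to its :class:`ConsensusState`.  Ties in the consensus score
    are broken toward the smaller dimension.  A failed fit drops that
    initialization with a warning; a candidate whose fits all fail raises.
    """
    candidates = sorted(int(c) for c in candidates)
    if not candidates:
        raise ValueError("no candidate dimensions given")
    if B < 1:
        raise ValueError("B must be >= 1")
    if candidates[-1] > min(dataset.modality_dims):
        raise ValueError(
            f"candidate d={candidates[-1]} exceeds the smallest modality "
            f"dimension {min(dataset.modality_dims)}"
        )
    fit_seeds, cluster_seeds = _derive_seeds(config.seed, len(candidates), B)
    states = {}
    for ci, dk in enumerate(candidates):
        models, labels_list, kept = [], [], []
        for b in range(B):
            cfg_b = replace(config, d=dk, seed=int(fit_seeds[ci, b]))
            try:
                fm = fit(dataset, cfg_b)
            except (np.linalg.LinAlgError, FloatingPointError) as exc:
                warnings.warn(
                    f"fit failed for d={dk}, init {b}: {exc}", RuntimeWarning
                )
                continue
            lab = cluster_embedding(
                fm.embedding, resolution=resolution,
                seed=int(cluster_seeds[ci, b]), n_neighbors=n_neighbors,
            )
            models.append(fm)
            labels_list.append(lab)
            kept.append(b)
        if not models:
            raise RuntimeError(f"all {B} fits failed for candidate d={dk}")
        labels = np.column_stack(labels_list)
        C = consensus_matrix(labels)
        conn = np.stack([connectivity_matrix(l) for l in labels_list])
        rmse = np.array([consensus_rmse(cb, C) for cb in conn])
        states[dk] = ConsensusState(
            candidate_d=dk,
            labels=labels,
            consensus=C,
            score=consensus_score(C),
            connectivity=conn,
            rmse=rmse,
            models=models,
            fit_seeds=fit_seeds[ci, kept],
            cluster_seeds=cluster_seeds[ci, kept],
        )
    d_star = candidates[0]
    for dk in candidates[1:]:
        if states[dk].score > states[d_star].score:
            d_star = dk
    return d_star, states


def fit_with_selection(
    dataset: MultiModalDataset,
    candidates,
    B: int,
    config: FitConfig,
    resolution: float = DEFAULT_RESOLUTION,
    n_neighbors: int = DEFAULT_NEIGHBORS,
):
    """Full pipeline: select d, then pick the best initialization.

    Returns ``(model, labels, d_star, states)`` -- the winning fitted model,
    its Louvain labels, the selected dimension, and all per-candidate
    consensus states.
    """
    d_star, states = select_latent_dimension(
        dataset, candidates, B, config, resolution, n_neighbors
    )
    st = states[d_star]
    b = st.best_init
    return st.models[b], st.labels[:, b], d_star, states
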