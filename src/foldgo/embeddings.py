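"""Biased-random-walk node embeddings and multimodal feature fusion.

Structural node embeddings follow the node2vec recipe: second-order random
walks on the contact graph biased by a return parameter ``p`` and an in-out
parameter ``q``, followed by skip-gram training with negative sampling on
the walk corpus. The walk transition rule gives a neighbor ``x`` of the
current node ``v`` (with previous node ``t``) unnormalized weight

    1/p  if x == t,
    1    if x is adjacent to t,
    1/q  otherwise,

normalized over the neighbors of ``v``; the first step is uniform.

The 30-d structural embedding of each residue is concatenated with its 26-d
one-hot identity to form the 56-d fused node features consumed by the model.
Protein-level sequence embeddings (1024-d vectors from a pretrained protein
language model) are consumed from files; a deterministic stub generates
stand-in vectors for fully offline runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numba
import numpy as np
from sklearn.base import BaseEstimator

from .structgraph import AA_TO_INDEX, ContactGraph, OneHotMatrix

SEQ_EMBEDDING_DIM = 1024


@dataclass(frozen=True)
class WalkParams:
    """Hyperparameters of the biased random walk and skip-gram stage."""

    p: float = 0.8
    q: float = 1.2
    walk_length: int = 30
    walks_per_node: int = 10
    window: int = 5
    epochs: int = 5
    negative: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")


@dataclass(frozen=True)
class TransitionDistribution:
    """Exact next-step distribution of the second-order walk."""

    current: int
    previous: int | None
    probs: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if self.probs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class NodeEmbedding:
    """N×dim real matrix of per-residue structural embeddings."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("embedding must be a 2-d matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("embedding entries must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FusedFeatures:
    """Concatenated node features: embedding block first, one-hot block last."""

    values: np.ndarray
    embed_dim: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape[1] <= self.embed_dim:
            raise ValueError("fused width must exceed the embedding width")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def embedding_block(self) -> np.ndarray:
        return self.values[:, : self.embed_dim]

    @property
    def onehot_block(self) -> np.ndarray:
        return self.values[:, self.embed_dim:]


def transition_distribution(
    graph: ContactGraph,
    previous: int | None,
    current: int,
    params: WalkParams,
) -> TransitionDistribution:
    """Exact biased-walk transition distribution out of ``current``."""
    nbrs = graph.neighbors()
    current_nbrs = nbrs[current]
    if current_nbrs.size == 0:
        return TransitionDistribution(current=current, previous=previous, probs={})
    if previous is None:
        w = np.ones(current_nbrs.size)
    else:
        prev_nbrs = set(int(x) for x in nbrs[previous])
        w = np.empty(current_nbrs.size)
        for k, x in enumerate(current_nbrs):
            if x == previous:
                w[k] = 1.0 / params.p
            elif int(x) in prev_nbrs:
                w[k] = 1.0
            else:
                w[k] = 1.0 / params.q
    w = w / w.sum()
    return TransitionDistribution(
        current=current,
        previous=previous,
        probs={int(x): float(pk) for x, pk in zip(current_nbrs, w)},
    )


class _WalkSampler:
    """Second-order walk sampler with cached per-(previous, current) tables."""

    def __init__(self, graph: ContactGraph, params: WalkParams):
        self.nbrs = graph.neighbors()
        self.nbr_sets = [set(int(x) for x in a) for a in self.nbrs]
        self.params = params
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def _cdf(self, previous: int, current: int) -> np.ndarray:
        key = (previous, current)
        cdf = self._cache.get(key)
        if cdf is None:
            nbrs = self.nbrs[current]
            prev_set = self.nbr_sets[previous]
            p, q = self.params.p, self.params.q
            w = np.array(
                [
                    1.0 / p if x == previous else (1.0 if int(x) in prev_set else 1.0 / q)
                    for x in nbrs
                ]
            )
            cdf = np.cumsum(w / w.sum())
            self._cache[key] = cdf
        return cdf

    def walk(self, start: int, rng: np.random.Generator) -> list[int]:
        seq = [start]
        nbrs = self.nbrs[start]
        if nbrs.size == 0:
            return seq
        seq.append(int(nbrs[rng.integers(nbrs.size)]))
        while len(seq) < self.params.walk_length:
            prev, cur = seq[-2], seq[-1]
            cur_nbrs = self.nbrs[cur]
            if cur_nbrs.size == 0:
                break
            cdf = self._cdf(prev, cur)
            seq.append(int(cur_nbrs[np.searchsorted(cdf, rng.random())]))
        return seq


def generate_walks(graph: ContactGraph, params: WalkParams) -> list[list[int]]:
    """Generate ``walks_per_node`` biased walks from every node.

    Walks from isolated nodes are the single start node. The corpus is fully
    reproducible under ``params.seed``.
    """
    if graph.n_nodes == 0:
        raise ValueError("graph must be nonempty")
    rng = np.random.default_rng(params.seed)
    sampler = _WalkSampler(graph, params)
    corpus: list[list[int]] = []
    for _ in range(params.walks_per_node):
        for start in range(graph.n_nodes):
            corpus.append(sampler.walk(start, rng))
    return corpus


@numba.njit(cache=False)
def _sgns_epoch(
    w_in: np.ndarray,
    w_out: np.ndarray,
    centers: np.ndarray,
    contexts: np.ndarray,
    negs: np.ndarray,
    lr0: float,
    lr_min: float,
    step0: int,
    total_steps: int,
) -> None:
    """One epoch of per-pair skip-gram negative-sampling SGD (in place)."""
    dim = w_in.shape[1]
    n_neg = negs.shape[1]
    grad = np.empty(dim)
    for i in range(centers.shape[0]):
        lr = lr0 * (1.0 - (step0 + i) / total_steps)
        if lr < lr_min:
            lr = lr_min
        c = centers[i]
        for k in range(n_neg + 1):
            if k == 0:
                target, label = contexts[i], 1.0
            else:
                target, label = negs[i, k - 1], 0.0
            dot = 0.0
            for d in range(dim):
                dot += w_in[c, d] * w_out[target, d]
            if dot > 8.0:
                s = 1.0
            elif dot < -8.0:
                s = 0.0
            else:
                s = 1.0 / (1.0 + np.exp(-dot))
            g = lr * (s - label)
            if k == 0:
                for d in range(dim):
                    grad[d] = g * w_out[target, d]
            else:
                for d in range(dim):
                    grad[d] += g * w_out[target, d]
            for d in range(dim):
                w_out[target, d] -= g * w_in[c, d]
        for d in range(dim):
            w_in[c, d] -= grad[d]


def _skipgram_pairs(corpus: list[list[int]], window: int) -> np.ndarray:
    """All (center, context) pairs within the window, as an (M, 2) array."""
    pairs: list[np.ndarray] = []
    for walk in corpus:
        arr = np.asarray(walk, dtype=np.int64)
        n = arr.size
        if n < 2:
            continue
        for off in range(1, min(window, n - 1) + 1):
            c = arr[:-off]
            t = arr[off:]
            pairs.append(np.column_stack([c, t]))
            pairs.append(np.column_stack([t, c]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(pairs, axis=0)


def train_node_embeddings(
    corpus: list[list[int]],
    n_nodes: int,
    dim: int = 30,
    params: WalkParams | None = None,
) -> NodeEmbedding:
    """Skip-gram with negative sampling over a walk corpus.

    Nodes absent from the corpus (isolated nodes) receive the zero vector so
    that row alignment with the residue chain is preserved. Training is
    single-threaded, vectorized over minibatches of (center, context) pairs,
    and reproducible under ``params.seed``.
    """
    if not corpus:
        raise ValueError("walk corpus must be nonempty")
    params = params or WalkParams()
    rng = np.random.default_rng(params.seed)

    pairs = _skipgram_pairs(corpus, params.window)
    if pairs.shape[0] == 0:
        return NodeEmbedding(values=np.zeros((n_nodes, dim)))
    counts = np.zeros(n_nodes)
    for walk in corpus:
        np.add.at(counts, np.asarray(walk, dtype=np.int64), 1.0)
    # nodes that never enter a training pair (isolated: singleton walks)
    # must come out as exact zero rows
    trained = np.zeros(n_nodes, dtype=bool)
    trained[pairs.ravel()] = True

    # unigram^0.75 negative-sampling distribution over nodes seen in walks
    noise = counts ** 0.75
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)

    bound = 0.5 / dim
    w_in = rng.uniform(-bound, bound, size=(n_nodes, dim))
    w_out = np.zeros((n_nodes, dim))

    n_pairs = pairs.shape[0]
    lr0, lr_min = 0.025, 1e-4
    total_steps = params.epochs * n_pairs
    step = 0
    for _ in range(params.epochs):
        order = rng.permutation(n_pairs)
        negs = np.searchsorted(
            noise_cdf, rng.random((n_pairs, params.negative))
        ).astype(np.int64)
        _sgns_epoch(
            w_in, w_out,
            pairs[order, 0], pairs[order, 1], negs,
            lr0, lr_min, step, total_steps,
        )
        step += n_pairs

    w_in[~trained] = 0.0
    return NodeEmbedding(values=canonicalize_embedding(w_in))


def canonicalize_embedding(values: np.ndarray) -> np.ndarray:
    """Rotate an embedding matrix onto its principal axes.

    Skip-gram embeddings are defined only up to an arbitrary rotation of the
    embedding space, which differs between independently trained models.
    When embeddings are trained per protein, raw coordinates are therefore
    not comparable across proteins; rotating each matrix onto its own
    principal axes (with a deterministic sign convention: each column's
    third moment is made non-negative) gives every protein the same
    geometry-derived coordinate frame. Rotation preserves row norms and all
    inter-node similarities, and zero rows stay zero.
    """
    values = np.asarray(values, dtype=float)
    if not np.any(values):
        return values
    _, _, vt = np.linalg.svd(values, full_matrices=True)
    rotated = values @ vt.T
    signs = np.sign(np.sum(rotated ** 3, axis=0))
    signs[signs == 0] = 1.0
    return rotated * signs


class Node2VecEmbedder(BaseEstimator):
    """Structural node embedder for a single contact graph.

    scikit-learn-style estimator: ``fit(graph)`` generates the biased walk
    corpus and trains the skip-gram model; the per-node embedding matrix is
    exposed as ``embedding_`` and returned by ``fit_transform``.

    Parameters mirror :class:`WalkParams` plus the embedding width ``dim``
    (30 by default, so fused features are 56-wide with the 26-d one-hot).
    """

    def __init__(
        self,
        dim: int = 30,
        p: float = 0.8,
        q: float = 1.2,
        walk_length: int = 30,
        walks_per_node: int = 10,
        window: int = 5,
        epochs: int = 5,
        negative: int = 5,
        seed: int = 0,
    ):
        self.dim = dim
        self.p = p
        self.q = q
        self.walk_length = walk_length
        self.walks_per_node = walks_per_node
        self.window = window
        self.epochs = epochs
        self.negative = negative
        self.seed = seed

    def _walk_params(self) -> WalkParams:
        return WalkParams(
            p=self.p,
            q=self.q,
            walk_length=self.walk_length,
            walks_per_node=self.walks_per_node,
            window=self.window,
            epochs=self.epochs,
            negative=self.negative,
            seed=self.seed,
        )

    def fit(self, graph: ContactGraph, y=None) -> "Node2VecEmbedder":
        params = self._walk_params()
        corpus = generate_walks(graph, params)
        self.embedding_ = train_node_embeddings(
            corpus, n_nodes=graph.n_nodes, dim=self.dim, params=params
        )
        return self

    def transform(self, graph: ContactGraph) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "embedding_")
        if graph.n_nodes != self.embedding_.values.shape[0]:
            raise ValueError("graph does not match the fitted embedding")
        return self.embedding_.values

    def fit_transform(self, graph: ContactGraph, y=None) -> np.ndarray:
        return self.fit(graph).transform(graph)


def fuse_features(emb: NodeEmbedding, onehot: OneHotMatrix) -> FusedFeatures:
    """Concatenate structural embedding and one-hot blocks column-wise."""
    if emb.values.shape[0] != onehot.values.shape[0]:
        raise ValueError(
            f"row mismatch: embedding has {emb.values.shape[0]} rows, "
            f"one-hot has {onehot.values.shape[0]}"
        )
    return FusedFeatures(
        values=np.concatenate([emb.values, onehot.values], axis=1),
        embed_dim=emb.dim,
    )


def stub_sequence_embedding(sequence: str, seed: int = 0) -> np.ndarray:
    """Deterministic 1024-d stand-in for a pretrained sequence embedding.

    Emulates the salient property of real language-model embeddings — they
    are strongly informative of sequence composition — without any learned
    weights: simple composition features (amino-acid frequencies plus a
    length term) are mapped through a fixed seed-derived random projection
    into 1024 dimensions, and a small hash-seeded pseudo-random component is
    added so distinct sequences with identical composition stay distinct.
    Identical (sequence, seed) pairs always map to identical vectors.
    """
    comp = np.zeros(len(AA_TO_INDEX) + 1)
    for aa in sequence.upper():
        comp[AA_TO_INDEX.get(aa, AA_TO_INDEX["X"])] += 1.0
    if len(sequence):
        comp[:-1] /= len(sequence)
    comp[-1] = len(sequence) / 100.0

    proj_rng = np.random.default_rng((seed * 2_654_435_761 + 97) & 0x7FFFFFFF)
    projection = proj_rng.standard_normal((comp.size, SEQ_EMBEDDING_DIM))
    projection /= np.sqrt(comp.size)

    digest = hashlib.blake2b(
        f"{seed}:{sequence}".encode(), digest_size=8
    ).digest()
    noise_rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return 8.0 * comp @ projection + 0.15 * noise_rng.standard_normal(
        SEQ_EMBEDDING_DIM
    )


def write_sequence_embeddings(
    table: dict[str, np.ndarray], path: str | Path
) -> None:
    """Write a protein-id → 1024-d vector table as TSV."""
    path = Path(path)
    with path.open("w") as fh:
        for pid, vec in table.items():
            vals = "\t".join(f"{x:.6g}" for x in np.asarray(vec, dtype=float))
            fh.write(f"{pid}\t{vals}\n")


def load_sequence_embeddings(path: str | Path) -> dict[str, np.ndarray]:
    table: dict[str, np.ndarray] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            table[parts[0]] = np.asarray(parts[1:], dtype=float)
    return table


def load_sequence_embedding(path: str | Path, protein_id: str) -> np.ndarray:
    """Load one protein's 1024-d sequence embedding from a TSV table."""
    table = load_sequence_embeddings(path)
    if protein_id not in table:
        raise KeyError(f"protein {protein_id!r} not found in {path}")
    vec = table[protein_id]
    if vec.size != SEQ_EMBEDDING_DIM:
        raise ValueError(
            f"embedding for {protein_id!r} has width {vec.size}, "
            f"expected {SEQ_EMBEDDING_DIM}"
        )
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"embedding for {protein_id!r} has non-finite entries")
    return vec


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_walk_corpus(corpus: list[list[int]], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(" ".join(str(n) for n in walk) for walk in corpus) + "\n"
    )
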