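"""Glue between the preprocessing stages and the classifier.

Turns (chain, contact graph, sequence embedding) triples into the
:class:`~foldgo.training.ProteinRecord` objects the model consumes: per
protein, a node2vec embedder is fitted on the contact graph, the structural
embedding is fused with the residue one-hot matrix, and the record carries
the 1024-d sequence vector alongside.
"""

from __future__ import annotations

import numpy as np

from .embeddings import (
    WalkParams,
    fuse_features,
    generate_walks,
    train_node_embeddings,
)
from .golabels import LabelMatrix
from .structgraph import ContactGraph, ResidueChain, encode_one_hot
from .training import ProteinRecord


def featurize_protein(
    chain: ResidueChain,
    graph: ContactGraph,
    dim: int = 30,
    params: WalkParams | None = None,
) -> np.ndarray:
    """Fused N×(dim+26) node-feature matrix for one protein."""
    params = params or WalkParams()
    corpus = generate_walks(graph, params)
    emb = train_node_embeddings(corpus, n_nodes=graph.n_nodes, dim=dim, params=params)
    return fuse_features(emb, encode_one_hot(chain)).values


def build_records(
    chains: dict[str, ResidueChain],
    graphs: dict[str, ContactGraph],
    seq_embeddings: dict[str, np.ndarray],
    dim: int = 30,
    params: WalkParams | None = None,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Featurize every protein; per-protein walk seeds derive from ``seed``."""
    params = params or WalkParams()
    records = []
    for i, (pid, chain) in enumerate(sorted(chains.items())):
        p = WalkParams(
            p=params.p, q=params.q, walk_length=params.walk_length,
            walks_per_node=params.walks_per_node, window=params.window,
            epochs=params.epochs, negative=params.negative,
            seed=(seed + 1_000_003 * i) & 0x7FFFFFFF,
        )
        records.append(
            ProteinRecord(
                protein_id=pid,
                graph=graphs[pid],
                features=featurize_protein(chain, graphs[pid], dim=dim, params=p),
                seq_embedding=np.asarray(seq_embeddings[pid], dtype=float),
            )
        )
    return records


def align_labels(
    records: list[ProteinRecord], matrix: LabelMatrix
) -> tuple[list[ProteinRecord], np.ndarray]:
    """Intersect records with a label matrix, preserving record order."""
    prot_idx = {p: i for i, p in enumerate(matrix.proteins)}
    kept = [r for r in records if r.protein_id in prot_idx]
    y = np.stack([matrix.values[prot_idx[r.protein_id]] for r in kept])
    return kept, y


def subset(
    records: list[ProteinRecord], y: np.ndarray, ids: set[str]
) -> tuple[list[ProteinRecord], np.ndarray]:
    """Select the records (and aligned label rows) whose ids are in ``ids``."""
    mask = [r.protein_id in ids for r in records]
    recs = [r for r, m in zip(records, mask) if m]
    return recs, y[np.asarray(mask, dtype=bool)]
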