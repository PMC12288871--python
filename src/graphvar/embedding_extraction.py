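"""Structural feature assembly for the pathogenicity classifier.

For each variant we embed the wild-type and the variant structure with a
trained graph autoencoder, keep both the pooled (mean over nodes) graph-level
vector and — at residue scope — the node embedding at the mutated position,
and derive cosine distances between wild type and variant at both levels.
The selected blocks are concatenated in a fixed canonical order and indexed
by a :class:`BlockRegistry`, which later scopes the per-block SHAP sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_autoencoder import GAEModel, encoder_forward, global_mean_pool
from .protein_graphs import ProteinGraph

__all__ = [
    "GraphEmbedding",
    "BlockRegistry",
    "FeatureRow",
    "BLOCK_ORDER",
    "embed_structure",
    "extract_node_embedding",
    "cosine_distance",
    "assemble_features",
]

#: canonical block order; SHAP plots stay comparable across runs
BLOCK_ORDER = ("cadd", "wt_pooled", "var_pooled", "wt_node", "var_node", "cos_pooled", "cos_node")

#: the blocks that require residue-scope node embeddings
NODE_BLOCKS = frozenset({"wt_node", "var_node", "cos_node"})

#: the structural-embedding blocks (what family-level SHAP sums range over)
STRUCTURAL_BLOCKS = ("wt_pooled", "var_pooled", "wt_node", "var_node")


@dataclass
class GraphEmbedding:
    pooled: np.ndarray          # (embedding_dim,)
    node_matrix: np.ndarray     # (n_nodes, embedding_dim)
    node_index: dict            # residue position -> row index (residue scope)


@dataclass
class BlockRegistry:
    """Ordered, disjoint (name, start, length) spans covering a feature vector."""

    blocks: list  # of (name, start, length)

    def __post_init__(self):
        names = [b[0] for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")
        expect = 0
        for name, start, length in self.blocks:
            if start != expect:
                raise ValueError(f"block {name!r} does not start at {expect}")
            expect = start + length
        self.total_width = expect

    def span(self, name: str) -> slice:
        for n, start, length in self.blocks:
            if n == name:
                return slice(start, start + length)
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [b[0] for b in self.blocks]

    def column_names(self) -> list:
        cols = []
        for name, _, length in self.blocks:
            cols.extend([f"{name}.{k}" for k in range(length)])
        return cols

    def to_dict(self) -> dict:
        return {"blocks": [list(b) for b in self.blocks]}

    @classmethod
    def from_dict(cls, d: dict) -> "BlockRegistry":
        return cls(blocks=[tuple(b) for b in d["blocks"]])


@dataclass
class FeatureRow:
    values: np.ndarray
    blocks: BlockRegistry


def embed_structure(model: GAEModel, graph: ProteinGraph) -> GraphEmbedding:
    """Run the encoder and pool: node matrix plus its column mean."""
    node_matrix = encoder_forward(graph, model)  # raises on scope mismatch
    index = {}
    if graph.scope == "residue":
        index = {pos: row for row, pos in enumerate(graph.node_index)}
    return GraphEmbedding(
        pooled=global_mean_pool(node_matrix),
        node_matrix=node_matrix,
        node_index=index,
    )


def extract_node_embedding(embedding: GraphEmbedding, position: int) -> np.ndarray:
    """Node embedding row at a 1-based residue position (the mutation site)."""
    if position not in embedding.node_index:
        raise ValueError(f"residue position {position} not present in the embedding")
    return embedding.node_matrix[embedding.node_index[position]]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v) in [0, 2]; defined as 1 when either vector is zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 1.0
    return float(1.0 - (u @ v) / (nu * nv))


def assemble_features(
    wt: GraphEmbedding,
    var: GraphEmbedding,
    position: int,
    feature_set,
    proxy_score: float | None = None,
) -> FeatureRow:
    """Concatenate the requested feature blocks in canonical order.

    ``feature_set`` is a subset of :data:`BLOCK_ORDER`. Node-level blocks
    require residue-scope embeddings (the node index maps residue positions);
    ``cadd`` requires ``proxy_score``.
    """
    feature_set = set(feature_set)
    unknown = feature_set - set(BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
    if "cadd" in feature_set and proxy_score is None:
        raise ValueError("feature set requests 'cadd' but no proxy score was provided")
    if feature_set & NODE_BLOCKS and not (wt.node_index and var.node_index):
        raise ValueError("node-level blocks require residue-scope embeddings")

    pieces: dict[str, np.ndarray] = {}
    if "cadd" in feature_set:
        pieces["cadd"] = np.array([float(proxy_score)])
    if "wt_pooled" in feature_set:
        pieces["wt_pooled"] = wt.pooled
    if "var_pooled" in feature_set:
        pieces["var_pooled"] = var.pooled
    if "wt_node" in feature_set:
        pieces["wt_node"] = extract_node_embedding(wt, position)
    if "var_node" in feature_set:
        pieces["var_node"] = extract_node_embedding(var, position)
    if "cos_pooled" in feature_set:
        pieces["cos_pooled"] = np.array([cosine_distance(wt.pooled, var.pooled)])
    if "cos_node" in feature_set:
        pieces["cos_node"] = np.array(
            [cosine_distance(extract_node_embedding(wt, position), extract_node_embedding(var, position))]
        )

    blocks, chunks, start = [], [], 0
    for name in BLOCK_ORDER:
        if name in pieces:
            vec = np.asarray(pieces[name], dtype=float)
            blocks.append((name, start, vec.size))
            chunks.append(vec)
            start += vec.size
    values = np.concatenate(chunks) if chunks else np.zeros(0)
    return FeatureRow(values=values, blocks=BlockRegistry(blocks))
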