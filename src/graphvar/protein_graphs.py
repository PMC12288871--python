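"""Convert protein structures into atomic- or residue-scoped graphs.

Residue scope: one node per residue placed at its alpha carbon; typed edges
for peptide bonds and distance-based residue-residue interactions (distance,
hydrophobic, aromatic, aromatic-sulphur, disulfide, cation-pi, hydrogen bond).
Node features are ``[x, y, z] + one-hot(aa, 20) + [donor, acceptor]`` (25).

Atomic scope: one node per atom; edges are covalent bonds inferred from
element covalent radii plus a tolerance; edge features are the min-max scaled
bond lengths of the graph. Node features are ``[x, y, z] + one-hot(element)``.

Multiple interaction types between the same node pair collapse to a single
undirected edge carrying the set of type tags; the encoders consume the
untyped adjacency, the tags are retained for inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .structure_io import AA_ALPHABET, ProteinStructure

__all__ = [
    "GraphConfig",
    "ProteinGraph",
    "build_residue_graph",
    "build_atomic_graph",
    "residue_node_features",
    "minmax_scale",
    "save_graph",
    "load_graph",
    "DONOR_RESIDUES",
    "ACCEPTOR_RESIDUES",
]

# residue-level hydrogen-bond chemistry: side-chain donors/acceptors at CA
# granularity (per-atom geometry is unavailable at residue scope)
_DONOR_ONLY = set("RKW")
_ACCEPTOR_ONLY = set("DE")
_DONOR_AND_ACCEPTOR = set("NQHSTYCM")
DONOR_RESIDUES = _DONOR_ONLY | _DONOR_AND_ACCEPTOR
ACCEPTOR_RESIDUES = _ACCEPTOR_ONLY | _DONOR_AND_ACCEPTOR

_HYDROPHOBIC = set("AVLIMFWPY")
_AROMATIC = set("FYWH")
_PI = set("FYW")
_SULPHUR = set("CM")
_CATION = set("KR")

#: single-bond covalent radii in Angstrom
COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}


@dataclass
class GraphConfig:
    """Thresholds (Angstrom) and vocabularies for graph construction."""

    scope: str = "residue"
    covalent_tolerance: float = 0.56
    residue_distance_threshold: float = 8.0
    hydrophobic_threshold: float = 5.0
    disulfide_threshold: float = 2.2
    disulfide_ca_fallback: float = 6.5
    aromatic_threshold: float = 7.0
    hbond_threshold: float = 3.5
    cation_pi_threshold: float = 6.0
    element_vocab: tuple = ("C", "N", "O", "S", "H")
    aa_vocab: str = AA_ALPHABET

    def __post_init__(self):
        if self.scope not in ("residue", "atomic"):
            raise ValueError(f"unknown scope {self.scope!r}")
        for name in (
            "covalent_tolerance", "residue_distance_threshold", "hydrophobic_threshold",
            "disulfide_threshold", "aromatic_threshold", "hbond_threshold",
            "cation_pi_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(set(self.element_vocab)) != len(self.element_vocab) or not self.element_vocab:
            raise ValueError("element_vocab must be non-empty and duplicate-free")
        if len(set(self.aa_vocab)) != len(self.aa_vocab) or not self.aa_vocab:
            raise ValueError("aa_vocab must be non-empty and duplicate-free")


@dataclass
class ProteinGraph:
    scope: str
    node_features: np.ndarray             # (n_nodes, d_in)
    node_index: list                      # node -> residue position (or (pos, atom name))
    edges: np.ndarray                     # (n_edges, 2), i < j, undirected
    edge_types: list                      # frozenset of type tags per edge
    edge_features: np.ndarray | None = None   # scalar per edge, atomic scope only

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return {tuple(e) for e in self.edges.tolist()}


def minmax_scale(values) -> np.ndarray:
    """(x - min) / (max - min) elementwise; constant input maps to all zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("minmax_scale requires a non-empty sequence")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def residue_node_features(residue, config: GraphConfig) -> np.ndarray:
    """25-vector ``[x, y, z, one-hot aa (20), donor, acceptor]``.

    Unknown residues (aa = X) get a zero one-hot block and no donor/acceptor
    flags, keeping the feature dimensionality fixed.
    """
    ca = residue.ca
    onehot = np.zeros(len(config.aa_vocab))
    idx = config.aa_vocab.find(residue.aa)
    if idx >= 0:
        onehot[idx] = 1.0
    flags = np.array(
        [float(residue.aa in DONOR_RESIDUES), float(residue.aa in ACCEPTOR_RESIDUES)]
    )
    return np.concatenate([ca.coords, onehot, flags])


def _add_edge(edge_map: dict, i: int, j: int, tag: str) -> None:
    key = (i, j) if i < j else (j, i)
    edge_map.setdefault(key, set()).add(tag)


def build_residue_graph(structure: ProteinStructure, config: GraphConfig | None = None) -> ProteinGraph:
    """Residue-scoped graph: one node per residue at its alpha carbon."""
    if config is None:
        config = GraphConfig(scope="residue")
    if config.scope != "residue":
        raise ValueError("config.scope must be 'residue'")
    if structure.n_residues == 0:
        raise ValueError("structure has no residues")

    seq = structure.sequence
    n = structure.n_residues
    feats = np.array([residue_node_features(r, config) for r in structure.residues])
    coords = structure.ca_coords()

    edge_map: dict = {}
    for i in range(n - 1):
        _add_edge(edge_map, i, i + 1, "peptide")

    if n > 1:
        dmat = squareform(pdist(coords))
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            d = dmat[i, j]
            ai, aj = seq[i], seq[j]
            if d <= config.residue_distance_threshold and j - i > 1:
                _add_edge(edge_map, i, j, "distance")
            if d <= config.hydrophobic_threshold and ai in _HYDROPHOBIC and aj in _HYDROPHOBIC:
                _add_edge(edge_map, i, j, "hydrophobic")
            if d <= config.aromatic_threshold and ai in _AROMATIC and aj in _AROMATIC:
                _add_edge(edge_map, i, j, "aromatic")
            if d <= config.aromatic_threshold and (
                (ai in _SULPHUR and aj in _PI) or (aj in _SULPHUR and ai in _PI)
            ):
                _add_edge(edge_map, i, j, "aromatic_sulphur")
            if d <= config.cation_pi_threshold and (
                (ai in _CATION and aj in _PI) or (aj in _CATION and ai in _PI)
            ):
                _add_edge(edge_map, i, j, "cation_pi")
            if d <= config.hbond_threshold and (
                (ai in DONOR_RESIDUES and aj in ACCEPTOR_RESIDUES)
                or (aj in DONOR_RESIDUES and ai in ACCEPTOR_RESIDUES)
            ):
                _add_edge(edge_map, i, j, "hbond")
            if ai == "C" and aj == "C":
                sgi = structure.residues[i].atom("SG")
                sgj = structure.residues[j].atom("SG")
                if sgi is not None and sgj is not None:
                    if np.linalg.norm(sgi.coords - sgj.coords) <= config.disulfide_threshold:
                        _add_edge(edge_map, i, j, "disulfide")
                elif d <= config.disulfide_ca_fallback:
                    _add_edge(edge_map, i, j, "disulfide")

    keys = sorted(edge_map)
    return ProteinGraph(
        scope="residue",
        node_features=feats,
        node_index=[r.position for r in structure.residues],
        edges=np.array(keys, dtype=int).reshape(-1, 2),
        edge_types=[frozenset(edge_map[k]) for k in keys],
        edge_features=None,
    )


def build_atomic_graph(structure: ProteinStructure, config: GraphConfig | None = None) -> ProteinGraph:
    """Atomic-scoped graph restricted to covalent edges.

    Two atoms are bonded iff their distance is at most the sum of their
    covalent radii plus ``covalent_tolerance``. Edge features are the min-max
    scaled bond lengths (per graph).
    """
    if config is None:
        config = GraphConfig(scope="atomic")
    if config.scope != "atomic":
        raise ValueError("config.scope must be 'atomic'")
    atoms = [(res.position, a) for res in structure.residues for a in res.atoms]
    if not atoms:
        raise ValueError("structure has no atoms")

    coords = np.array([a.coords for _, a in atoms])
    elements = [a.element for _, a in atoms]
    vocab = list(config.element_vocab)
    feats = np.zeros((len(atoms), 3 + len(vocab)))
    feats[:, :3] = coords
    for k, el in enumerate(elements):
        if el in vocab:
            feats[k, 3 + vocab.index(el)] = 1.0

    radii = np.array([COVALENT_RADII.get(el, max(COVALENT_RADII.values())) for el in elements])
    max_cut = 2 * radii.max() + config.covalent_tolerance
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=max_cut, output_type="ndarray")
    edges, dists = [], []
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        if d <= radii[i] + radii[j] + config.covalent_tolerance:
            edges.append((min(i, j), max(i, j)))
            dists.append(d)
    order = np.argsort([e[0] * len(atoms) + e[1] for e in edges]) if edges else []
    edges = [edges[k] for k in order]
    dists = [dists[k] for k in order]

    return ProteinGraph(
        scope="atomic",
        node_features=feats,
        node_index=[(pos, a.name) for pos, a in atoms],
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        edge_types=[frozenset({"covalent"})] * len(edges),
        edge_features=minmax_scale(dists) if dists else np.zeros(0),
    )


def save_graph(graph: ProteinGraph, prefix) -> None:
    """Persist a graph as nodes.csv + edges.csv + header JSON (``prefix`` stem)."""
    import pandas as pd

    prefix = str(prefix)
    nodes = pd.DataFrame(graph.node_features, columns=[f"f{i}" for i in range(graph.node_features.shape[1])])
    nodes.insert(0, "node_index", [str(ix) for ix in graph.node_index])
    nodes.to_csv(prefix + ".nodes.csv", index=False)
    edges = pd.DataFrame(graph.edges, columns=["i", "j"])
    edges["types"] = ["|".join(sorted(t)) for t in graph.edge_types]
    if graph.edge_features is not None:
        edges["feature"] = graph.edge_features
    edges.to_csv(prefix + ".edges.csv", index=False)
    with open(prefix + ".json", "w") as fh:
        json.dump({"scope": graph.scope, "n_nodes": graph.n_nodes, "n_edges": graph.n_edges}, fh)


def load_graph(prefix) -> ProteinGraph:
    import pandas as pd

    prefix = str(prefix)
    with open(prefix + ".json") as fh:
        header = json.load(fh)
    nodes = pd.read_csv(prefix + ".nodes.csv")
    edges = pd.read_csv(prefix + ".edges.csv")
    feat_cols = [c for c in nodes.columns if c.startswith("f")]
    return ProteinGraph(
        scope=header["scope"],
        node_features=nodes[feat_cols].to_numpy(float),
        node_index=list(nodes["node_index"]),
        edges=edges[["i", "j"]].to_numpy(int).reshape(-1, 2),
        edge_types=[frozenset(t.split("|")) for t in edges["types"]],
        edge_features=edges["feature"].to_numpy(float) if "feature" in edges else None,
    )
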