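"""SMILES -> featurized molecular graph.

Atoms become nodes, bonds become undirected edges (heavy atoms only;
hydrogens stay implicit in the H-count feature).  Besides node/edge feature
matrices the graph carries two structural descriptors consumed by the model:

* ``hop_dist`` — all-pairs shortest-path bond counts (BFS), ``inf`` between
  disconnected fragments; drives the exponential decay attention mask.
* ``rw_encoding`` — for each node the probability that a uniform random walk
  returns to it in exactly k steps, k = 1..K; used as a structural positional
  encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from rdkit import Chem

__all__ = ["FeatureConfig", "MolecularGraph", "build_graph", "random_walk_encoding"]


@dataclass(frozen=True)
class FeatureConfig:
    """Which atom/bond descriptors enter the feature matrices.

    The defaults cover the descriptors RDKit exposes for drug-like organic
    molecules; swap the lists to change the one-hot vocabularies.
    """

    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
    hybridizations: tuple[str, ...] = ("SP", "SP2", "SP3")
    max_degree: int = 5
    max_h_count: int = 4
    rw_steps: int = 20

    @property
    def node_dim(self) -> int:
        # every one-hot carries a trailing "other" bucket
        return (len(self.elements) + 1) + (self.max_degree + 2) + 1 \
            + (self.max_h_count + 2) + (len(self.hybridizations) + 1) + 2

    @property
    def edge_dim(self) -> int:
        # bond order one-hot (single/double/triple/aromatic), conjugated,
        # in-ring, stereo flag
        return 4 + 3


@dataclass
class MolecularGraph:
    node_features: np.ndarray    # (n, d_node)
    edge_list: np.ndarray        # (m, 2) undirected pairs, i < j
    edge_features: np.ndarray    # (m, d_edge)
    hop_dist: np.ndarray         # (n, n), inf across components
    rw_encoding: np.ndarray      # (n, K)
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_list.shape[0]


def _one_hot(value, choices) -> list[float]:
    v = [0.0] * (len(choices) + 1)
    try:
        v[list(choices).index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0  # "other" bucket
    return v


def _atom_features(atom: Chem.Atom, cfg: FeatureConfig) -> list[float]:
    feats = _one_hot(atom.GetSymbol(), cfg.elements)
    feats += _one_hot(min(atom.GetDegree(), cfg.max_degree), range(cfg.max_degree + 1))
    feats.append(float(atom.GetFormalCharge()))
    feats += _one_hot(min(atom.GetTotalNumHs(), cfg.max_h_count),
                      range(cfg.max_h_count + 1))
    feats += _one_hot(str(atom.GetHybridization()), cfg.hybridizations)
    feats.append(float(atom.GetIsAromatic()))
    feats.append(float(atom.IsInRing()))
    return feats


_BOND_ORDER = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def _bond_features(bond: Chem.Bond) -> list[float]:
    order = [0.0] * 4
    order[_BOND_ORDER.get(bond.GetBondType(), 0)] = 1.0
    return order + [
        float(bond.GetIsConjugated()),
        float(bond.IsInRing()),
        float(bond.GetStereo() != Chem.BondStereo.STEREONONE),
    ]


def _adjacency(n: int, edge_list: np.ndarray) -> csr_matrix:
    if len(edge_list) == 0:
        return csr_matrix((n, n))
    i, j = edge_list[:, 0], edge_list[:, 1]
    data = np.ones(2 * len(edge_list))
    return csr_matrix(
        (data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)
    )


def hop_distances(n: int, edge_list: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path hop counts; inf between components."""
    if n == 0:
        return np.zeros((0, 0))
    return shortest_path(_adjacency(n, edge_list), method="D", unweighted=True)


def random_walk_encoding(graph_or_adj, steps: int) -> np.ndarray:
    """k-step return probabilities of a uniform random walk, k = 1..steps.

    Entry (i, k-1) is the diagonal of the k-th power of the degree-normalized
    transition matrix P = D^-1 A.  Rows of isolated nodes are all zero.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if isinstance(graph_or_adj, MolecularGraph):
        adj = _adjacency(graph_or_adj.n_atoms, graph_or_adj.edge_list)
    else:
        adj = csr_matrix(np.asarray(graph_or_adj, float))
    n = adj.shape[0]
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0)
    P = (adj.multiply(inv[:, None])).toarray()
    out = np.zeros((n, steps))
    Pk = np.eye(n)
    for k in range(steps):
        Pk = Pk @ P
        out[:, k] = np.diag(Pk)
    return out


def build_graph(smiles: str, feature_config: FeatureConfig | None = None) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Raises ValueError for unparseable strings and zero-atom inputs.  Output
    is deterministic for a fixed atom order of the input.
    """
    cfg = feature_config or FeatureConfig()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError(f"zero-atom SMILES: {smiles!r}")

    node_features = np.array(
        [_atom_features(a, cfg) for a in mol.GetAtoms()], float
    )
    edges, efeats = [], []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
        efeats.append(_bond_features(b))
    edge_list = np.array(edges, int).reshape(-1, 2)
    edge_features = np.array(efeats, float).reshape(-1, cfg.edge_dim)

    hop = hop_distances(n, edge_list)
    rw = random_walk_encoding(_adjacency(n, edge_list).toarray(), cfg.rw_steps)
    return MolecularGraph(
        node_features=node_features,
        edge_list=edge_list,
        edge_features=edge_features,
        hop_dist=hop,
        rw_encoding=rw,
        smiles=smiles,
    )
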