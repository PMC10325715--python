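"""Wiring diagrams, shared-partner similarity and connectivity embedding.

The synapse table becomes an adjacency matrix ``A`` whose (i, j) entry is
the number of synaptic sites from presynaptic neuron i to postsynaptic
neuron j.  From it:

* ``A @ A.T`` counts common targets (shared outputs) for every neuron pair,
  ``A.T @ A`` counts common inputs, and their sum is the combined
  connectivity-similarity matrix;
* a spectral embedding of the combined matrix places neurons with similar
  in/out partners close together;
* aggregating over cell types with a synapse-count threshold yields the
  type-level wiring diagram, laid out with a seeded spring model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import networkx as nx
import numpy as np
import pandas as pd

from .tables import ConnectomeError, ConnectomeTable


@dataclass
class WiringDiagram:
    """Weighted directed graph view of a connectome table.

    Nodes are ordered by neuron id; ``A[i, j]`` sums ``n_sites`` over all
    synapse rows from node i to node j.  Diagonal entries appear only for
    flagged autapses.
    """

    neuron_ids: np.ndarray
    cell_types: np.ndarray
    A: np.ndarray

    @property
    def n(self) -> int:
        return len(self.neuron_ids)

    def index_of(self, neuron_id: int) -> int:
        return int(np.searchsorted(self.neuron_ids, neuron_id))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, t in zip(self.neuron_ids, self.cell_types):
            g.add_node(int(nid), cell_type=str(t))
        rows, cols = np.nonzero(self.A)
        for i, j in zip(rows, cols):
            g.add_edge(int(self.neuron_ids[i]), int(self.neuron_ids[j]), weight=int(self.A[i, j]))
        return g


@dataclass
class SimilaritySet:
    """Shared-output / shared-input / combined similarity matrices."""

    common_output: np.ndarray  # A A'
    common_input: np.ndarray  # A' A
    combined: np.ndarray  # A A' + A' A
    neuron_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def build_wiring_diagram(table: ConnectomeTable) -> WiringDiagram:
    """Adjacency matrix of a validated connectome table.

    Node order is sorted by neuron id; dangling synapse references raise
    with the offending rows listed.
    """
    table.validate()
    ids = np.sort(table.neurons["neuron_id"].to_numpy())
    types = table.neurons.set_index("neuron_id")["cell_type"].loc[ids].to_numpy()
    n = len(ids)
    index = pd.Series(np.arange(n), index=ids)
    A = np.zeros((n, n), dtype=np.int64)
    if len(table.synapses):
        i = index.loc[table.synapses["pre_id"]].to_numpy()
        j = index.loc[table.synapses["post_id"]].to_numpy()
        np.add.at(A, (i, j), table.synapses["n_sites"].to_numpy())
    return WiringDiagram(neuron_ids=ids, cell_types=types, A=A)


def compute_similarities(w: WiringDiagram, include_autapses: bool = False) -> SimilaritySet:
    """Exact integer shared-partner matrices.

    Autapses (diagonal of ``A``) are excluded by default: a self-synapse is
    not a shared partner in the pairwise sense.
    """
    A = w.A.astype(np.int64)
    if not include_autapses:
        A = A.copy()
        np.fill_diagonal(A, 0)
    co = A @ A.T
    ci = A.T @ A
    return SimilaritySet(
        common_output=co, common_input=ci, combined=co + ci, neuron_ids=w.neuron_ids
    )


def embed_neurons(s: SimilaritySet, k: int = 100, seed: int = 0) -> pd.DataFrame:
    """Spectral embedding of the combined similarity matrix.

    Coordinates are the top-``k`` eigenvectors of the (positive
    semidefinite) combined matrix scaled by the square root of their
    eigenvalues, with a deterministic sign convention (the
    largest-magnitude entry of each eigenvector is positive).  The first
    two dimensions serve as the planar projection.  ``k >= N`` is clipped
    to N-1 with a warning.  ``seed`` is accepted for interface symmetry;
    the dense eigendecomposition is deterministic.
    """
    del seed
    C = np.asarray(s.combined, dtype=float)
    n = C.shape[0]
    if not np.allclose(C, C.T):
        raise ValueError("combined similarity matrix must be symmetric")
    if k >= n:
        warn(f"k={k} >= N={n}; clipping to {n - 1}")
        k = max(n - 1, 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:k]
    lam, V = evals[order], evecs[:, order]
    lam = np.clip(lam, 0.0, None)  # PSD up to round-off
    for col in range(V.shape[1]):  # deterministic sign
        imax = int(np.argmax(np.abs(V[:, col])))
        if V[imax, col] < 0:
            V[:, col] = -V[:, col]
    coords = V * np.sqrt(lam)
    cols = [f"dim{i + 1}" for i in range(coords.shape[1])]
    out = pd.DataFrame(coords, columns=cols)
    out.insert(0, "neuron_id", s.neuron_ids if len(s.neuron_ids) == n else np.arange(n))
    return out


@dataclass
class TypeGraph:
    """Cell-type level wiring diagram with a display threshold."""

    graph: nx.DiGraph
    min_synapses: float

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def weight(self, pre: str, post: str) -> int:
        return int(self.graph.edges[pre, post]["weight"])


def build_type_graph(w: WiringDiagram, min_synapses: float = 10) -> TypeGraph:
    """Aggregate the adjacency matrix by cell type.

    Edge weight is the total synapse count between the type pair; only
    edges with weight strictly greater than ``min_synapses`` are retained
    ("more than 10 synapses" in the default display convention).
    """
    g = nx.DiGraph()
    types = np.unique(w.cell_types)
    g.add_nodes_from(types)
    df = pd.DataFrame(
        {
            "pre": np.repeat(w.cell_types, w.n),
            "post": np.tile(w.cell_types, w.n),
            "weight": w.A.ravel(),
        }
    )
    agg = df.groupby(["pre", "post"], sort=True)["weight"].sum()
    for (pre, post), weight in agg.items():
        if weight > min_synapses:
            g.add_edge(pre, post, weight=int(weight))
    return TypeGraph(graph=g, min_synapses=min_synapses)


def layout_type_graph(tg: TypeGraph, seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded force-directed (spring) layout of the type graph.

    Heavier edges pull their endpoints closer in expectation; positions are
    reproducible under a fixed seed.
    """
    pos = nx.spring_layout(tg.graph, weight="weight", seed=seed)
    return {node: np.asarray(p, dtype=float) for node, p in pos.items()}


def combine_layouts(
    type_positions: dict[str, np.ndarray],
    embedding: pd.DataFrame,
    cell_types: pd.Series,
    scale: float = 0.1,
) -> pd.DataFrame:
    """Per-neuron display positions: type anchor plus scaled embedding offset.

    Each neuron sits at the spring-layout position of its cell type,
    shifted by ``scale`` times its (max-norm standardized) first two
    embedding dimensions; ``scale=0`` collapses neurons onto their type
    anchors.
    """
    offsets = embedding[["dim1", "dim2"]].to_numpy(dtype=float)
    norm = np.abs(offsets).max()
    if norm > 0:
        offsets = offsets / norm
    rows = []
    for (_, row), off in zip(embedding.iterrows(), offsets):
        nid = int(row["neuron_id"])
        t = cell_types.loc[nid]
        if t not in type_positions:
            raise ConnectomeError(f"no type anchor for cell type {t!r}")
        p = type_positions[t] + scale * off
        rows.append({"neuron_id": nid, "cell_type": t, "x": p[0], "y": p[1]})
    return pd.DataFrame(rows)
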