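"""Feed-forwardness of a directed synaptic wiring diagram.

A directed synaptic graph is feed-forward to the extent that no synapse
participates in a directed cycle of information flow.  The statistic used
here is the number of synaptic sites on cycle-participating edges: an edge
lies on some directed cycle exactly when its two endpoints belong to the
same strongly connected component, which makes the statistic independent of
any particular topological order.  Significance is assessed against random
wiring diagrams that keep the neurons, the multiset of connected pairs and
the per-pair synapse counts but randomize synaptic direction; the one-sided
p-value asks whether the observed cycle involvement is unusually low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .wiring import WiringDiagram

RANDOMIZATION_MODES = ("per_pair", "per_synapse")


@dataclass
class ForwardnessResult:
    """Cycle-participating edges, the synapse-count statistic and a
    topological order of the acyclic condensation."""

    feedback_edges: list[tuple[int, int]]
    feedback_synapses: int
    condensation_order: list[list[int]]  # SCCs (neuron ids) in topological order

    @property
    def is_dag(self) -> bool:
        return self.feedback_synapses == 0


@dataclass
class PermutationTestResult:
    observed: int
    null_distribution: np.ndarray
    p_value: float
    n_perm: int
    mode: str
    seed: int

    def null_summary(self) -> dict:
        nd = self.null_distribution
        return {
            "min": float(nd.min()),
            "median": float(np.median(nd)),
            "max": float(nd.max()),
            "mean": float(nd.mean()),
        }


# ---------------------------------------------------------------------------
# Pair-level representation (the permutation loop operates on this)
# ---------------------------------------------------------------------------

@dataclass
class _PairSet:
    n: int
    u: np.ndarray  # u < v, unordered connected pairs
    v: np.ndarray
    w: np.ndarray  # total synaptic sites per pair
    w_forward: np.ndarray  # sites currently directed u -> v
    self_w: int  # autapse sites (always cycle-participating)

    @property
    def total_synapses(self) -> int:
        return int(self.w.sum()) + self.self_w


def _pairs_from_diagram(w: WiringDiagram) -> _PairSet:
    A = w.A
    upper = np.triu(A, 1)
    lower = np.tril(A, -1).T
    tot = upper + lower
    iu, iv = np.nonzero(tot)
    return _PairSet(
        n=w.n,
        u=iu,
        v=iv,
        w=tot[iu, iv].astype(np.int64),
        w_forward=upper[iu, iv].astype(np.int64),
        self_w=int(np.trace(A)),
    )


def _stat_from_directed(n: int, src: np.ndarray, dst: np.ndarray, wts: np.ndarray) -> int:
    """Synaptic sites on edges whose endpoints share a strongly connected
    component (plus nothing else: autapse weights are added by callers)."""
    if len(src) == 0:
        return 0
    g = sparse.csr_matrix((np.ones(len(src), dtype=np.int8), (src, dst)), shape=(n, n))
    _, labels = connected_components(g, directed=True, connection="strong")
    return int(wts[labels[src] == labels[dst]].sum())


def _directed_arrays(p: _PairSet, w_forward: np.ndarray):
    fwd = w_forward > 0
    bwd = (p.w - w_forward) > 0
    src = np.concatenate([p.u[fwd], p.v[bwd]])
    dst = np.concatenate([p.v[fwd], p.u[bwd]])
    wts = np.concatenate([w_forward[fwd], (p.w - w_forward)[bwd]])
    return src, dst, wts


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def find_feedback(w: WiringDiagram) -> ForwardnessResult:
    """Identify all cycle-participating edges of a wiring diagram.

    An edge is a feedback edge iff it lies on some directed cycle,
    equivalently iff its endpoints are in the same strongly connected
    component (an autapse is a cycle of length one).  The statistic sums
    ``n_sites`` over feedback edges.  The condensation of the graph is
    acyclic; its topological order is returned as a list of components
    (each a list of neuron ids) and, for a DAG, is a valid node order with
    every edge pointing forward.
    """
    g = w.to_networkx()
    sccs = list(nx.strongly_connected_components(g))
    comp_of = {node: ci for ci, comp in enumerate(sccs) for node in comp}
    feedback_edges = []
    feedback_synapses = 0
    for a, b, data in g.edges(data=True):
        if comp_of[a] == comp_of[b]:  # includes self-loops
            feedback_edges.append((a, b))
            feedback_synapses += data["weight"]
    cond = nx.condensation(g, scc=sccs)
    order = [sorted(cond.nodes[ci]["members"]) for ci in nx.topological_sort(cond)]
    return ForwardnessResult(
        feedback_edges=sorted(feedback_edges),
        feedback_synapses=int(feedback_synapses),
        condensation_order=order,
    )


def randomize_directions(
    w: WiringDiagram, mode: str = "per_pair", rng: np.random.Generator | None = None
) -> WiringDiagram:
    """Randomize synaptic direction while conserving the pair structure.

    ``per_pair`` assigns each connected pair's entire synapse bundle one
    uniform-random direction (never creating reciprocal pairs);
    ``per_synapse`` directs each synaptic site independently with
    probability 1/2 (reciprocal pairs can arise).  Autapses are left in
    place.  The node set, the multiset of unordered connected pairs and
    the per-pair synapse totals are conserved exactly.
    """
    if mode not in RANDOMIZATION_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {RANDOMIZATION_MODES}")
    rng = np.random.default_rng() if rng is None else rng
    p = _pairs_from_diagram(w)
    if mode == "per_pair":
        flip = rng.random(len(p.w)) < 0.5
        w_forward = np.where(flip, p.w, 0)
    else:
        w_forward = rng.binomial(p.w, 0.5)
    A = np.zeros_like(w.A)
    src, dst, wts = _directed_arrays(p, w_forward)
    A[src, dst] = wts
    np.fill_diagonal(A, np.diag(w.A))
    return WiringDiagram(neuron_ids=w.neuron_ids, cell_types=w.cell_types, A=A)


def permutation_test(
    w: WiringDiagram,
    n_perm: int = 10_000,
    mode: str = "per_pair",
    seed: int = 0,
) -> PermutationTestResult:
    """Direction-randomization test for feed-forwardness.

    The null distribution is the feedback-synapse statistic over ``n_perm``
    direction-randomized copies of the wiring diagram; the one-sided
    p-value for "observed is unusually low" uses the permutation-inclusive
    add-one formula ``p = (1 + #{null <= observed}) / (1 + n_perm)``, so
    ties count toward the p-value and p is never zero.
    """
    if mode not in RANDOMIZATION_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {RANDOMIZATION_MODES}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    p = _pairs_from_diagram(w)
    observed = _stat_from_directed(p.n, *_directed_arrays(p, p.w_forward)) + p.self_w
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        if mode == "per_pair":
            flip = rng.random(len(p.w)) < 0.5
            w_forward = np.where(flip, p.w, 0)
        else:
            w_forward = rng.binomial(p.w, 0.5)
        null[i] = _stat_from_directed(p.n, *_directed_arrays(p, w_forward)) + p.self_w
    p_value = float((1 + int((null <= observed).sum())) / (1 + n_perm))
    return PermutationTestResult(
        observed=int(observed),
        null_distribution=null,
        p_value=p_value,
        n_perm=n_perm,
        mode=mode,
        seed=seed,
    )


def type_one_error_rate(
    w: WiringDiagram,
    n_replicates: int = 200,
    n_perm: int = 99,
    mode: str = "per_pair",
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Calibration of the feed-forwardness test under its own null.

    Each replicate direction-randomizes the input diagram (so the null
    hypothesis holds by construction) and runs the permutation test on the
    randomized copy; the fraction of replicates with p < ``alpha`` should
    be close to ``alpha`` for a calibrated (slightly conservative) test.
    """
    rng = np.random.default_rng(seed)
    p_values = np.empty(n_replicates)
    for r in range(n_replicates):
        null_input = randomize_directions(w, mode=mode, rng=rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        p_values[r] = permutation_test(null_input, n_perm=n_perm, mode=mode, seed=sub_seed).p_value
    rate = float((p_values < alpha).mean())
    return {"rate": rate, "p_values": p_values, "n_replicates": n_replicates, "alpha": alpha}
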