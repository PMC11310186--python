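"""Maximal-clique enumeration (Bron-Kerbosch with pivoting) and clique-based
edge re-weighting.

Edges whose endpoints share a large maximal clique mark strongly knit patient
groups; re-weighting the adjacency by clique size lets the encoder's
weighted-mean aggregation lean on those neighbours. An edge between nodes i
and j that lie together in a maximal clique of size c+1 receives weight c;
when a pair belongs to several maximal cliques, the sizes are combined by a
configurable aggregator (max by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import PatientGraph

AGGREGATORS = ("max", "sum", "count")


@dataclass
class CliqueSet:
    """Maximal cliques of a graph, each a sorted tuple of node indices.

    ``source_graph_hash`` binds the set to the topology it was enumerated
    from, so stale clique sets cannot silently re-weight a different graph.
    """

    cliques: list[tuple[int, ...]]
    source_graph_hash: str

    def __len__(self) -> int:
        return len(self.cliques)

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.cliques], dtype=np.int64)


def _bron_kerbosch_pivot(
    adj: list[set[int]],
    r: set[int],
    p: set[int],
    q: set[int],
    out: list[tuple[int, ...]],
) -> None:
    # R: clique under construction; P: candidates; Q: already-processed nodes
    # that would only regenerate previously reported cliques.
    if not p and not q:
        out.append(tuple(sorted(r)))
        return
    # Pivot maximising |P ∩ N(pivot)|, ties broken by lowest node index.
    pivot, best = -1, -1
    for u in sorted(p | q):
        score = len(p & adj[u])
        if score > best:
            pivot, best = u, score
    for v in sorted(p - adj[pivot]):
        _bron_kerbosch_pivot(adj, r | {v}, p & adj[v], q & adj[v], out)
        p.remove(v)
        q.add(v)


def enumerate_maximal_cliques(g: PatientGraph) -> CliqueSet:
    """List every maximal clique of ``g`` exactly once.

    Isolated nodes are reported as singleton maximal cliques. Weights are
    ignored (topology only). Output is normalised: each clique sorted
    internally, cliques sorted lexicographically, so runs are reproducible.
    """
    n = g.n_nodes
    csr = g.adjacency.tocsr()
    adj = [set(csr.indices[csr.indptr[i] : csr.indptr[i + 1]].tolist()) for i in range(n)]
    out: list[tuple[int, ...]] = []
    _bron_kerbosch_pivot(adj, set(), set(range(n)), set(), out)
    out.sort()
    return CliqueSet(cliques=out, source_graph_hash=g.topology_hash())


def assign_clique_weights(
    g: PatientGraph, cs: CliqueSet, aggregator: str = "max"
) -> PatientGraph:
    """Re-weight every edge by the maximal cliques containing both endpoints.

    For a clique of size c+1, each of its edges contributes c; contributions
    of multiple cliques to one edge are combined by ``aggregator``:

    - ``max``   : the largest containing clique (default),
    - ``sum``   : sum of (size - 1) over containing cliques,
    - ``count`` : number of containing maximal cliques.

    The edge set is never changed, only weights; any weights from a previous
    call are reset first, so the operation is idempotent. Every edge lies in
    some maximal clique of size >= 2, hence weights stay >= 1.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; choose from {AGGREGATORS}")
    if cs.source_graph_hash != g.topology_hash():
        raise ValueError("stale clique set: it was not enumerated from this graph")

    n = g.n_nodes
    base = g.adjacency.copy().astype(np.int64)
    base.data[:] = 1  # reset any prior weighting; weights apply to the binary support
    weights = sp.dok_matrix((n, n), dtype=np.int64)
    for clique in cs.cliques:
        c = len(clique) - 1
        if c < 1:
            continue
        contrib = 1 if aggregator == "count" else c
        for a_idx in range(len(clique)):
            for b_idx in range(a_idx + 1, len(clique)):
                i, j = clique[a_idx], clique[b_idx]
                if aggregator == "max":
                    if contrib > weights[i, j]:
                        weights[i, j] = contrib
                        weights[j, i] = contrib
                else:
                    weights[i, j] += contrib
                    weights[j, i] += contrib
    weighted = weights.tocsr()
    # Support is identical by construction; keep weight 1 on any edge no clique
    # touched (cannot happen for a well-formed clique set, but stay safe).
    new_adj = base.maximum(weighted.multiply(base.astype(bool)))
    return g.with_adjacency(new_adj)
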